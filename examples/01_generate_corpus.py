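"""Generate a synthetic EMR-like corpus and look at one document.

Real annotated EMR corpora for CVD risk factors are private, so the
package ships a generator that plants risk-factor mentions (with BIO tags
carrying type + temporal attribute) into filler text and labels each
document by a known rule: CVD-positive iff at least 3 distinct risk-factor
types carry an active (Continue/During) temporal attribute.
"""

from endcnn import SynthConfig, generate_corpus

corpus = generate_corpus(SynthConfig(n_docs=659, seed=13))
print(f"splits: train={len(corpus.train)} dev={len(corpus.dev)} test={len(corpus.test)}")
prevalence = sum(d.document.label for d in corpus.all) / len(corpus.all)
print(f"CVD prevalence: {prevalence:.3f}")

doc = corpus.train[0]
print("\ncharacters:", doc.sentence.chars)
print("tags:      ", " ".join(doc.sentence.tags))
print("label:", doc.document.label, "(1 = CVD under the planted rule)")
for m in doc.mentions:
    print(f"  mention {m.surface!r}: type={m.rf_type} temporal={m.temporal} "
          f"span=[{m.start},{m.end})")
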