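# docrex — document-level biomedical relation extraction

Document-level corpora such as the BioCreative V chemical–disease relation
(CDR) set annotate relations per *concept pair per document*, not per
sentence: whether the evidence for a chemical-induced disease (CID)
assertion sits inside one sentence or spans several is unknown.  Pipelines
that split such corpora into intra- and inter-sentence instances with
heuristic rules (e.g. "co-sentential mentions at token distance < 10")
discard real evidence and mislabel context.

`docrex` implements the alternative: **one instance per candidate entity
pair**, built from the contiguous block of sentences running from the first
to the last sentence that mentions either target concept, labeled directly
with the pair's document-level gold relation.  Because instances of
different pairs can share identical text, a pretreatment step makes the
target pair explicit before classification:

* **replacement** — target chemical/disease mentions become the uniform
  words `chemical` / `disease`, other entity mentions become `entity`;
* **addition** — target mentions keep their surface form inside boundary
  markers, `[[ … ]]` for chemicals and `<< … >>` for diseases.

Classification uses a k-stack, h-head transformer encoder over WordPiece
tokens (implemented here in NumPy, with exact hand-derived gradients):

```
S⁰   = tok_emb + seg_emb + pos_emb                        (input, n×d)
O_i  = softmax(S W_iᵠ (S W_iᴷ)ᵀ / √l) S W_iⱽ              (head i, l = d/h)
M    = LN(S^{k-1} + [O_1; …; O_h] Wᴼ)                     (multi-head + residual)
S^k  = LN(M + ReLU(M W₁ + b₁) W₂ + b₂)                    (position-wise FFN, m = 4d)
c    = Wᵖʳᵉᵈ s_cls                                        (classifier on [CLS])
```

The full-scale published configuration is k=12, h=12, d=768, m=3072 with
pretrained weights; `docrex` trains any size from scratch on CPU and can
ingest externally converted pretrained weights through
`docrex.model.load_pretrained`.  Evaluation reports per-class and micro
precision/recall/F1 (negative class excluded from the micro average),
5-run averages, and a breakdown over 50-token instance-length bins.

A synthetic-corpus generator (`docrex.synthetic`) emits PubTator-format
documents with exact mention offsets, document-level gold relations and
planted lexical cues, so the whole pipeline is testable without corpus
downloads.

## Worked example

```python
import docrex as dx
from docrex.estimator import TransformerRelationClassifier

# construct instances from the worked-example document
doc = dx.figure1_fixture()
instances = dx.build_document_instances(doc)
print(f"{len(instances)} instances, "
      f"{sum(i.label == 'CID' for i in instances)} positive")
inst = dx.figure2_instance()
print(dx.apply_replacement(inst).text)
print(dx.apply_addition(inst).text)

# train a tiny encoder on a synthetic corpus with planted cues
train = dx.build_corpus_instances(
    dx.generate_corpus(dx.SyntheticConfig(n_docs=340, seed=11)))[:500]
held = dx.build_corpus_instances(
    dx.generate_corpus(dx.SyntheticConfig(n_docs=120, seed=999)))
clf = TransformerRelationClassifier(n_stacks=2, n_heads=2, d_model=32,
                                    max_len=64, n_epochs=3, batch_size=16,
                                    learning_rate=1e-3, random_state=0)
clf.fit([dx.apply_replacement(i).text for i in train],
        [i.label for i in train])
pred = clf.predict([dx.apply_replacement(i).text for i in held])
m = dx.evaluate([i.label for i in held], list(pred))
cm = m.per_class["CID"]
print(f"held-out CID  P={cm.precision:.1f}%  R={cm.recall:.1f}%  "
      f"F1={cm.f1:.1f}%  (n={cm.support})")
```

prints

```
8 instances, 2 positive
Two cases of chemical entity: a cause for disease
Two cases of [[ amisulpride ]] overdose: a cause for << prolonged QT syndrome >>
held-out CID  P=100.0%  R=100.0%  F1=100.0%  (n=56)
```

The fixture document has 2 chemical and 4 disease concepts, hence
2 × 4 = 8 candidate pairs; its two gold CID relations label exactly two
instances positive.  The two printed sentences show the replacement and
addition pretreatments applied to the same instance.  The tiny
from-scratch encoder (k=2, h=2, d=32, 3 epochs) recovers the planted
relation cue perfectly on a held-out synthetic split — a learnability
check, not a claim about real corpora.

A command-line interface mirrors the library:
`docrex synth`, `docrex corpus validate`, `docrex preprocess`,
`docrex stats`, `docrex pretreat`, `docrex train`, `docrex bins`,
`docrex attn`, `docrex model describe`.

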