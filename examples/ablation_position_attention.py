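"""Position-aware vs. word-level attention on a position-only task.

Builds the position-sensitive corpus — the label depends solely on whether a
cue token sits immediately before or after the cannabis mention, with the
same cue also planted elsewhere so bag-of-words counts are identical across
labels — then compares the two attention mechanisms and a bag-of-words
control.
"""

import cannarel as cr
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

lex = cr.fixture_lexicon(seed=0)
corpus = cr.position_sensitive_task(lex, cr.GeneratorConfig(n_records=200, seed=0))
train_recs, test_recs = train_test_split(
    corpus, test_size=0.25, stratify=[r.label for r in corpus], random_state=0
)

vec = CountVectorizer(token_pattern=r"\S+")
bow = LogisticRegression(max_iter=2000).fit(
    vec.fit_transform([r.text for r in train_recs]), [r.label for r in train_recs]
)
acc = bow.score(vec.transform([r.text for r in test_recs]), [r.label for r in test_recs])
print(f"bag-of-words accuracy: {100 * acc:.1f}%  (chance = 50%)")

for variant in ("full", "vanilla_attention"):
    cfg = cr.TrainConfig(epochs=10, learning_rate=0.005, seed=0, variant=variant)
    result = cr.train(train_recs, lex, cfg)
    f1 = cr.evaluate(result.pipeline, test_recs).f1
    print(f"{variant:<20} held-out F1: {f1:.1f}")

# Bag-of-words stays near chance because token counts carry no signal; the
# sequence models recover the label from token order and entity-relative
# positions, with position-aware attention at least matching word-level
# attention.
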