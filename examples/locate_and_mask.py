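"""Locate cannabis/depression mentions by fuzzy lexicon matching, then mask them.

Builds the bundled fixture lexicon, runs the edit-distance n-gram matcher on
two short texts (one with clean mentions, one with slang misspellings), and
prints the located spans and the masked token sequences the classifier sees.
"""

import cannarel as cr

lex = cr.fixture_lexicon(seed=0)
print(f"lexicon: {len(lex)} surfaces, longest = {lex.max_surface_tokens} tokens\n")

for text in [
    "I treat my depression with weed",
    "been smokin chronic all week and feel depresed",
]:
    tokens = cr.tokenize(text)
    spans = cr.match_entities(tokens, lex)  # default threshold: distance <= 0.2
    print(f"text:   {text}")
    for s in sorted(spans):
        print(
            f"  span [{s.start},{s.end}) {s.category.value:<10} "
            f"matched {s.matched_surface!r} at normalized distance {s.distance:.3f}"
        )
    masked = cr.mask_entities(tokens, spans)
    print(f"masked: {' '.join(masked.tokens)}\n")

# Each span reports which lexicon surface it matched and how far it was:
# distance 0 is an exact hit, 0.067 = one character edit in 15 ("smokin
# chronic" vs "smoking chronic").  Masking replaces each mention with a
# category token so the classifier learns category-level patterns.
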