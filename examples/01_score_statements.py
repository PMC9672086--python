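"""Polarity-score free-text statements with the three pooling operators.

Builds a five-word lexicon with one modifier and one negator, scores a
few Danish-style statements, and prints the pooled polarity under sum,
arithmetic-mean and partitioned-signed-geometric-mean pooling.
"""

from bedmot import Lexicon, score_document

lexicon = Lexicon(
    valences={"god": 3.0, "fantastisk": 5.0, "dårlig": -2.0, "håb": 2.0, "skam": -3.0},
    modifiers={"meget": 1.5},
    negators={"ikke"},
)

statements = [
    "Jeg har håb. Det er meget god!",     # modifier + exclamation boost
    "ikke god. Jeg føler skam.",          # negation flips 'god'
    "er det ikke god?",                   # interrogative: negation suppressed
    "helt andre ord her",                 # no lexicon hits -> neutral
]

for text in statements:
    print(f"\n{text!r}")
    for method in ("sum", "mean", "gmean"):
        res = score_document(text, lexicon, method)
        print(f"  {method:>5}: {res.value:+.3f}  ({res.n_scored}/{res.n_tokens} tokens scored)")

# The signs agree across pooling methods; magnitudes differ because sum
# grows with statement length while mean/gmean normalise by token count.
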