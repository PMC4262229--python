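"""Score the bundled anaphase-promoting module prediction.

The package ships the 13-protein anaphase-promoting module detected on the
DIP yeast network together with the curated 16-protein complex.  The
neighborhood-affinity score NA = |overlap|²/(|p|·|b|) quantifies the match
(NA ≥ 0.2 counts as matched); the matching rate is the percentage of
predicted proteins that belong to the reference complex.
"""

from maefmd import matching_rate, na_score
from maefmd.datasets import anaphase_example

predicted, reference = anaphase_example()
p, b = predicted[0], reference[0]

print(f"predicted module: {len(p)} proteins")
print(f"curated complex:  {len(b)} proteins")
print(f"overlap:          {len(p & b)} proteins")
print(f"NA score:         {na_score(p, b):.4f}")
print(f"matching rate:    {matching_rate(p, b):.1f}%")
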