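"""Synthesize a review and run per-domain sign tests.

Loads the packaged synthetic housing-improvement review (10 studies, 3
outcome domains), collapses each study's outcomes to one direction per
domain with the 70% majority rule, then tests each domain's positive vs
negative vote split against a fair-coin null.
"""

from edplot import describe, run_sign_tests, synthesize_all
from edplot.io import housing_example

records, studies = housing_example()
print(f"{len(records)} outcomes across {len(studies)} studies\n")

syntheses = synthesize_all(records, studies)
for result in run_sign_tests(syntheses):
    print(describe(result))
    print()

# Each block shows the vote split (studies with unclear/conflicting
# direction are excluded from the test but counted), the exact two-tailed
# p-value, and the interpretation caveats.  A small p means the observed
# imbalance of positive vs negative study-level directions would be
# unlikely if either direction were equally probable.
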