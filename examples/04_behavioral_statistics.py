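"""Behavioral analysis of a simulated cohort's stress self-reports.

Generates the default 8 ASD + 5 neurotypical cohort and runs the paired
Wilcoxon signed-rank test comparing pre- vs post-stressor 5-point scores
for stress-induction blocks 2-4 (no report precedes block 1). Negative Z
means post-stressor scores are higher, i.e. the stressor worked.
"""

import stressbci as sb
from stressbci.stats import wilcoxon_signed_rank

cohort = sb.generate_cohort(n_asd=8, n_nt=5, seed=1)
for block in range(2, 5):
    pre = [r.pre_post_pairs()[block - 2][0] for _, _, r in cohort]
    post = [r.pre_post_pairs()[block - 2][1] for _, _, r in cohort]
    z, p = wilcoxon_signed_rank(pre, post)
    print(f"block {block}: mean pre {sum(pre) / len(pre):.2f}, "
          f"mean post {sum(post) / len(post):.2f}, Z = {z:.2f}, p = {p:.4g}")
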