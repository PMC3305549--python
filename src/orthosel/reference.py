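"""Reference −lnL tables from a published 11S-globulin selection analysis.

These are the worked-example inputs for the likelihood-ratio machinery: the
negative log-likelihoods of nested branch-specific models (one-, two-,
three- and six-ratio) fitted to the 11S seed-storage globulin gene family,
and of the branch-site Model A null/alternative pairs for the five tested
foreground branches (A–E).  Feeding them through :func:`orthosel.seltest.lrt`
reproduces the published significance verdicts; the statistics and p-values
are computed here, not stored.

Degrees of freedom for the branch-model comparisons equal the difference in
the number of ω classes; branch-site tests use df = 1.
"""

from __future__ import annotations

#: −lnL of the nested branch-specific models and their ω-class counts
BRANCH_MODEL_MINUS_LNL: dict[str, tuple[float, int]] = {
    "one-ratio": (38214.64, 1),
    "two-ratio": (38210.14, 2),
    "three-ratio": (38209.98, 3),
    "six-ratio": (38182.58, 6),
}

#: branch-site Model A: foreground branch -> (−lnL null, −lnL alternative)
BRANCH_SITE_MINUS_LNL: dict[str, tuple[float, float]] = {
    "A": (46859.30, 46851.6),
    "B": (46854.00, 46837.66),
    "C": (46852.38, 46831.76),
    "D": (46859.11, 46842.30),
    "E": (46859.33, 46859.33),
}

#: the published verdict for each branch-model comparison:
#: (null model, alternative model, p-value threshold, significant?)
BRANCH_MODEL_VERDICTS: list[tuple[str, str, float, bool]] = [
    ("one-ratio", "two-ratio", 0.01, True),
    ("one-ratio", "three-ratio", 0.01, True),
    ("two-ratio", "three-ratio", 0.05, False),
    ("one-ratio", "six-ratio", 0.01, True),
]

#: foreground branches reported as under positive selection (p < 0.01)
BRANCH_SITE_SIGNIFICANT: dict[str, bool] = {
    "A": True, "B": True, "C": True, "D": True, "E": False,
}
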