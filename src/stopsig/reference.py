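"""Published summary statistics of the reference study, and their recomputation.

The reference study compared 30 elite handball players ("expert") with 30
physically active recreational athletes ("control") on a stop-signal task
performed with the hands and with the feet. Its raw trial data are not
bundled here; what is bundled are the published group-level summaries
(means, SDs, ns, F ratios, correlations), from which the whole inferential
layer — effect sizes, noncentral-t intervals, one-tailed t-tests, Bayes
factors under both the default and the informed Cauchy prior, and the
correlation analyses — can be recomputed deterministically.

:func:`reproduce_printed` is the single entry point; the acceptance script
and the ``stopsig reproduce-printed`` CLI command both call it.
"""

from __future__ import annotations

from typing import NamedTuple

from . import inference

__all__ = ["GroupSummary", "REFERENCE", "reproduce_printed"]


class GroupSummary(NamedTuple):
    mean: float
    sd: float
    n: int


#: Published group-level summaries. SSRT and two-choice RT in milliseconds.
REFERENCE = {
    "ssrt": {
        "hands": {
            "expert": GroupSummary(229.36, 32.83, 30),
            "control": GroupSummary(261.52, 39.00, 30),
        },
        "feet": {
            "expert": GroupSummary(259.5, 41.6, 30),
            "control": GroupSummary(276.74, 38.4, 30),
        },
    },
    "crt": {  # two-choice RT, pooled over groups (no group difference reported)
        "hands": GroupSummary(408.02, 36.03, 60),
        "feet": GroupSummary(423.58, 28.87, 60),
    },
    "anova_ssrt": {  # published F ratios, df = (1, 58)
        "effector": (26.54, 1, 58),
        "group": (7.89, 1, 58),
        "interaction": (2.87, 1, 58),
    },
    "correlations": {  # hands-feet SSRT correlations
        "pooled": (0.63, 60),
        "expert": (0.67, 30),
        "control": (0.54, 30),
    },
    "slowing": {  # no-signal RT / two-choice RT
        "hands": {"mean": 1.298, "sd": 0.259, "min": 0.955, "max": 2.058},
        "feet": {"mean": 1.239, "sd": 0.229, "min": 0.712, "max": 2.047},
    },
}

#: Cauchy priors used in the published Bayesian t-tests: (location, scale).
DEFAULT_PRIOR = (0.0, 0.707)
INFORMED_PRIOR = (0.5, 0.5)
ROBUSTNESS_SCALES = (0.5, 0.707, 1.0)


def reproduce_printed(conf_level: float = 0.95) -> dict:
    """Recompute every printed-summary statistic from the published summaries.

    Per effector: Cohen's d with its noncentral-t CI, the one-tailed pooled
    t-test (direction: control minus expert positive, i.e. expert
    superiority), Bayes factors under the default Cauchy(0, 0.707) and
    informed Cauchy(0.5, 0.5) priors (one-sided), and a robustness sweep.
    Plus partial eta squared recovered from the published F ratios and the
    Fisher-z correlation layer.
    """
    out: dict = {"effectors": {}, "anova": {}, "correlations": {}}
    for effector, groups in REFERENCE["ssrt"].items():
        e, c = groups["expert"], groups["control"]
        # expert first: positive d/t mean experts are faster to stop
        eff = inference.pooled_cohens_d(e.mean, e.sd, e.n, c.mean, c.sd, c.n, conf_level)
        tt = inference.independent_t_test(e.mean, e.sd, e.n, c.mean, c.sd, c.n, side="positive")
        bf_default = inference.jzs_bayes_factor(tt.t, e.n, c.n, *DEFAULT_PRIOR, side="positive")
        bf_informed = inference.jzs_bayes_factor(tt.t, e.n, c.n, *INFORMED_PRIOR, side="positive")
        sweep = inference.bf_robustness(tt.t, e.n, c.n, ROBUSTNESS_SCALES, side="positive")
        out["effectors"][effector] = {
            "expert": e._asdict(),
            "control": c._asdict(),
            "d": eff.d,
            "d_ci": (eff.ci_low, eff.ci_high),
            "t": tt.t,
            "df": tt.df,
            "p_one_sided": tt.p,
            "bf10_default": bf_default.bf10,
            "bf10_informed": bf_informed.bf10,
            "bf_robustness": {r.prior_scale: r.bf10 for r in sweep},
        }
    for effect, (F, df1, df2) in REFERENCE["anova_ssrt"].items():
        out["anova"][effect] = {
            "F": F,
            "df": (df1, df2),
            "partial_eta_sq": inference.partial_eta_squared(F, df1, df2),
        }
    r_pooled, n_pooled = REFERENCE["correlations"]["pooled"]
    out["correlations"]["pooled_one_sided"] = _corr_dict(
        inference.pearson_ci(r_pooled, n_pooled, conf_level, "one_sided")
    )
    for grp in ("expert", "control"):
        r, n = REFERENCE["correlations"][grp]
        out["correlations"][grp] = _corr_dict(inference.pearson_ci(r, n, conf_level, "two_sided"))
    re_, ne = REFERENCE["correlations"]["expert"]
    rc, nc = REFERENCE["correlations"]["control"]
    z, p = inference.compare_independent_correlations(re_, ne, rc, nc, "one_sided")
    out["correlations"]["expert_vs_control"] = {"z": z, "p": p}
    return out


def _corr_dict(c: inference.CorrelationResult) -> dict:
    return {"r": c.r, "n": c.n, "ci": (c.ci_low, c.ci_high), "sidedness": c.sidedness}
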