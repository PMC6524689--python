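"""Model/Results layer: the whole group analysis behind one `fit()` call.

`StopSignalModel` wraps a per-participant summary table (one row per
participant x effector, as produced by :func:`stopsig.ssrt.summarize_sessions`)
and `fit()` runs the complete inferential pipeline of a two-group,
two-effector stop-signal study: the 2 x 2 between-within ANOVA on SSRT and on
two-choice RT, per-effector expert-vs-control contrasts (one-tailed t,
Cohen's d with noncentral-t CI, Bayes factors under the default and informed
Cauchy priors plus a robustness sweep), the hands-feet SSRT correlation layer,
and the strategic-slowing comparison. The returned `StopSignalResults` holds
everything and renders a statsmodels-style `summary()` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import inference, ssrt, task
from .exceptions import StopsigError

__all__ = ["StopSignalModel", "StopSignalResults"]

REQUIRED_COLUMNS = ("participant_id", "group", "effector", "crt_mean", "ssrt")


class StopSignalModel:
    """Two-group, two-effector stop-signal analysis model.

    Parameters
    ----------
    summary : DataFrame
        One row per participant x effector with at least the columns
        ``participant_id, group, effector, crt_mean, ssrt`` (plus
        ``slowing_index`` for the slowing comparison).
    group_order : (str, str)
        The (reference, comparison) group labels. Contrasts are reported as
        comparison minus reference, so with ``("expert", "control")`` a
        positive SSRT difference means experts stop faster.
    """

    def __init__(self, summary: pd.DataFrame, group_order: tuple[str, str] = ("expert", "control")):
        missing = [c for c in REQUIRED_COLUMNS if c not in summary.columns]
        if missing:
            raise StopsigError(f"summary table lacks columns {missing}")
        groups = set(summary["group"].unique())
        if groups != set(group_order):
            raise StopsigError(f"expected groups {group_order}, found {sorted(groups)}")
        effectors = sorted(summary["effector"].unique())
        if len(effectors) != 2:
            raise StopsigError(f"expected exactly 2 effectors, found {effectors}")
        counts = summary.groupby(["participant_id"])["effector"].nunique()
        if (counts != 2).any():
            bad = counts[counts != 2].index.tolist()
            raise StopsigError(f"participants missing an effector: {bad}")
        self.summary_table = summary.reset_index(drop=True)
        self.group_order = group_order
        self.effectors = effectors

    @classmethod
    def from_sessions(
        cls,
        sessions: list[task.SessionResult],
        basis: str = "go_trials",
        group_order: tuple[str, str] = ("expert", "control"),
    ) -> "StopSignalModel":
        return cls(ssrt.summarize_sessions(sessions, basis), group_order)

    @classmethod
    def from_trials_csv(cls, path, basis: str = "go_trials",
                        group_order: tuple[str, str] = ("expert", "control")) -> "StopSignalModel":
        return cls.from_sessions(task.read_trials_csv(path), basis, group_order)

    @classmethod
    def from_summary_csv(cls, path,
                         group_order: tuple[str, str] = ("expert", "control")) -> "StopSignalModel":
        return cls(pd.read_csv(path), group_order)

    # ------------------------------------------------------------------

    def _group_summary(self, effector: str, column: str) -> dict[str, inference.EffectSize]:
        df = self.summary_table
        out = {}
        for g in self.group_order:
            vals = df[(df["group"] == g) & (df["effector"] == effector)][column].to_numpy()
            out[g] = (float(vals.mean()), float(vals.std(ddof=1)), len(vals))
        return out

    def fit(
        self,
        conf_level: float = 0.95,
        priors: Sequence[tuple[float, float]] = ((0.0, 0.707), (0.5, 0.5)),
        robustness_scales: Sequence[float] = (0.5, 0.707, 1.0),
        side: str = "positive",
    ) -> "StopSignalResults":
        df = self.summary_table
        anova = {
            dv: inference.mixed_anova_2x2(df, dv=dv, within="effector",
                                          subject="participant_id", between="group")
            for dv in ("ssrt", "crt_mean")
        }

        contrasts: dict[str, dict] = {}
        for effector in self.effectors:
            gs = self._group_summary(effector, "ssrt")
            (m1, s1, n1) = gs[self.group_order[0]]
            (m2, s2, n2) = gs[self.group_order[1]]
            eff = inference.pooled_cohens_d(m1, s1, n1, m2, s2, n2, conf_level)
            tt = inference.independent_t_test(m1, s1, n1, m2, s2, n2, side=side)
            bfs = [
                inference.jzs_bayes_factor(tt.t, n1, n2, loc, scale, side)
                for loc, scale in priors
            ]
            sweep = inference.bf_robustness(tt.t, n1, n2, robustness_scales, side)
            contrasts[effector] = {
                "groups": {g: {"mean": v[0], "sd": v[1], "n": v[2]} for g, v in gs.items()},
                "effect_size": eff,
                "t_test": tt,
                "bayes_factors": bfs,
                "robustness": sweep,
            }

        wide = df.pivot_table(index=["participant_id", "group"], columns="effector",
                              values="ssrt").reset_index()
        e1, e2 = self.effectors
        correlations = {"pooled": self._corr_block(wide, e1, e2, conf_level)}
        for g in self.group_order:
            correlations[g] = self._corr_block(wide[wide["group"] == g], e1, e2, conf_level)
        z, p = inference.compare_independent_correlations(
            correlations[self.group_order[0]]["r"], correlations[self.group_order[0]]["n"],
            correlations[self.group_order[1]]["r"], correlations[self.group_order[1]]["n"],
            "one_sided",
        )
        correlations["group_comparison"] = {"z": z, "p": p}

        slowing = None
        if "slowing_index" in df.columns:
            slowing = {}
            for effector in self.effectors:
                sub = df[df["effector"] == effector]["slowing_index"]
                gs = self._group_summary(effector, "slowing_index")
                (m1, s1, n1) = gs[self.group_order[0]]
                (m2, s2, n2) = gs[self.group_order[1]]
                tt = inference.independent_t_test(m1, s1, n1, m2, s2, n2, "two_sided")
                bf = inference.jzs_bayes_factor(tt.t, n1, n2, 0.0, 0.707, "two_sided")
                slowing[effector] = {
                    "mean": float(sub.mean()),
                    "sd": float(sub.std(ddof=1)),
                    "min": float(sub.min()),
                    "max": float(sub.max()),
                    "group_t": tt,
                    "group_bf01": bf.bf01,
                }

        return StopSignalResults(
            model=self,
            anova=anova,
            contrasts=contrasts,
            correlations=correlations,
            slowing=slowing,
            conf_level=conf_level,
        )

    @staticmethod
    def _corr_block(wide: pd.DataFrame, e1: str, e2: str, conf_level: float) -> dict:
        x, y = wide[e1].to_numpy(dtype=float), wide[e2].to_numpy(dtype=float)
        r = float(np.corrcoef(x, y)[0, 1])
        ci = inference.pearson_ci(r, len(x), conf_level, "two_sided")
        return {"r": r, "n": len(x), "ci": (ci.ci_low, ci.ci_high)}


def _fmt_p(p: float) -> str:
    return "< 0.001" if p < 0.001 else f"{p:.3f}"


@dataclass
class StopSignalResults:
    """Fitted results: ANOVA tables, contrasts, correlations, slowing."""

    model: StopSignalModel
    anova: dict[str, inference.AnovaResult]
    contrasts: dict[str, dict]
    correlations: dict
    slowing: dict | None
    conf_level: float

    def summary(self) -> str:
        g1, g2 = self.model.group_order
        lines = [
            "Stop-Signal Expertise Analysis",
            "=" * 70,
            f"groups: {g1} vs {g2} (contrast = {g2} - {g1})   "
            f"effectors: {', '.join(self.model.effectors)}",
            "",
        ]
        for dv, res in self.anova.items():
            lines.append(f"Mixed ANOVA on {dv} (between: group, within: effector)")
            for name, e in res.effects.items():
                lines.append(
                    f"  {name:<12} F({e.df1},{e.df2}) = {e.F:7.2f}   "
                    f"p = {_fmt_p(e.p):>7}   eta_p^2 = {e.partial_eta_sq:.3f}"
                )
            lines.append("")
        lines.append(f"Per-effector SSRT contrasts ({g2} - {g1}, one-tailed)")
        for effector, c in self.contrasts.items():
            eff, tt = c["effect_size"], c["t_test"]
            lines.append(
                f"  {effector:<6} t({tt.df}) = {tt.t:5.2f}, p = {_fmt_p(tt.p)}, "
                f"d = {eff.d:.2f}, {int(self.conf_level*100)}% CI "
                f"({eff.ci_low:.3f}, {eff.ci_high:.3f})"
            )
            for bf in c["bayes_factors"]:
                lines.append(
                    f"         BF10 = {bf.bf10:8.2f}  "
                    f"[Cauchy({bf.prior_location}, {bf.prior_scale}), {bf.side}]"
                )
        lines.append("")
        e1, e2 = self.model.effectors
        pooled = self.correlations["pooled"]
        lines.append(
            f"{e1}-{e2} SSRT correlation: r = {pooled['r']:.2f} "
            f"(n = {pooled['n']}, CI {pooled['ci'][0]:.2f}..{pooled['ci'][1]:.2f})"
        )
        cmp_ = self.correlations["group_comparison"]
        lines.append(
            f"  group comparison of correlations: z = {cmp_['z']:.2f}, p = {_fmt_p(cmp_['p'])}"
        )
        if self.slowing:
            lines.append("")
            lines.append("Strategic slowing (no-signal RT / two-choice RT)")
            for effector, s in self.slowing.items():
                lines.append(
                    f"  {effector:<6} mean = {s['mean']:.3f} (sd {s['sd']:.3f}), "
                    f"group BF01 = {s['group_bf01']:.2f}"
                )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serializable report of every fitted quantity."""
        out = {
            "group_order": list(self.model.group_order),
            "effectors": list(self.model.effectors),
            "conf_level": self.conf_level,
            "anova": {
                dv: {
                    name: {"F": e.F, "df1": e.df1, "df2": e.df2, "p": e.p,
                           "partial_eta_sq": e.partial_eta_sq}
                    for name, e in res.effects.items()
                }
                for dv, res in self.anova.items()
            },
            "contrasts": {},
            "correlations": {
                k: (dict(v) if isinstance(v, dict) else v)
                for k, v in self.correlations.items()
            },
        }
        for effector, c in self.contrasts.items():
            eff, tt = c["effect_size"], c["t_test"]
            out["contrasts"][effector] = {
                "groups": c["groups"],
                "d": eff.d,
                "d_ci": [eff.ci_low, eff.ci_high],
                "t": tt.t,
                "df": tt.df,
                "p": tt.p,
                "side": tt.side,
                "bayes_factors": [
                    {"bf10": b.bf10, "prior_location": b.prior_location,
                     "prior_scale": b.prior_scale, "side": b.side,
                     "numerical_error": b.numerical_error}
                    for b in c["bayes_factors"]
                ],
                "robustness": [
                    {"prior_scale": b.prior_scale, "bf10": b.bf10}
                    for b in c["robustness"]
                ],
            }
        if self.slowing is not None:
            out["slowing"] = {
                effector: {
                    "mean": s["mean"], "sd": s["sd"], "min": s["min"], "max": s["max"],
                    "group_t": s["group_t"].t, "group_p": s["group_t"].p,
                    "group_bf01": s["group_bf01"],
                }
                for effector, s in self.slowing.items()
            }
        return out
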