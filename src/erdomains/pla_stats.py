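"""Per-cell proximity-ligation-assay (PLA) ratio statistics.

The quantification procedure: normalize the PLA and EGFP channels by their
across-all-cells medians, gate cells on EGFP expression (strictly greater
than the threshold; by default applied to the RAW EGFP intensity, where a
fixed absolute threshold such as 5000 is meaningful), form the per-cell
PLA/EGFP ratio, and compare conditions.  An F test for equal variances is
always computed and reported, but inference always uses Welch's two-tailed
t test, which is valid whether or not the variances are equal — this avoids
the conditional-testing pitfall of choosing the test based on the F result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import PLA_CONDITIONS, PlaCellTable

DEFAULT_EGFP_GATE = 5000.0


@dataclass
class ConditionStats:
    n_cells_total: int
    n_cells_gated: int
    median_pla: float
    median_egfp: float
    mean_ratio: float
    sd_ratio: float


@dataclass
class PlaResult:
    per_condition: dict  # condition -> ConditionStats
    effect: float        # mutant mean ratio / wt mean ratio
    f_stat: float
    f_p: float
    welch_t: float
    welch_df: float
    welch_p: float       # two-tailed
    egfp_gate: float
    gate_on: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cond, cs in self.per_condition.items():
            rows.append(
                {
                    "condition": cond,
                    "n_cells_total": cs.n_cells_total,
                    "n_cells_gated": cs.n_cells_gated,
                    "median_pla": cs.median_pla,
                    "median_egfp": cs.median_egfp,
                    "mean_ratio": cs.mean_ratio,
                    "sd_ratio": cs.sd_ratio,
                    "effect_mut_over_wt": self.effect,
                    "F": self.f_stat,
                    "F_p": self.f_p,
                    "welch_t": self.welch_t,
                    "welch_df": self.welch_df,
                    "welch_p_two_tailed": self.welch_p,
                    "egfp_gate": self.egfp_gate,
                    "gate_on": self.gate_on,
                }
            )
        return pd.DataFrame(rows)


def _welch_df(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
    return (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))


def pla_ratio_test(
    cells: PlaCellTable,
    egfp_gate: float = DEFAULT_EGFP_GATE,
    gate_on: str = "raw",
) -> PlaResult:
    """Median-normalize channels, gate on EGFP, and test the per-cell
    PLA/EGFP ratio between conditions.

    ``gate_on='raw'`` (default) keeps cells whose raw EGFP intensity is
    strictly greater than ``egfp_gate``; ``gate_on='normalized'`` applies the
    same strict gate to the median-normalized EGFP channel instead (use a
    gate on the order of 1 in that mode).
    """
    if gate_on not in ("raw", "normalized"):
        raise ValueError("gate_on must be 'raw' or 'normalized'")
    if egfp_gate <= 0:
        raise ValueError("egfp_gate must be > 0")
    df = cells.cells
    pla = df["pla"].to_numpy(dtype=float)
    egfp = df["egfp"].to_numpy(dtype=float)
    med_pla = np.median(pla)
    med_egfp = np.median(egfp)
    if med_pla <= 0 or med_egfp <= 0:
        raise ValueError("channel medians must be positive for normalization")
    norm_pla = pla / med_pla
    norm_egfp = egfp / med_egfp

    gated = (egfp if gate_on == "raw" else norm_egfp) > egfp_gate

    per_condition: dict[str, ConditionStats] = {}
    ratios: dict[str, np.ndarray] = {}
    for cond in PLA_CONDITIONS:
        in_cond = (df["condition"] == cond).to_numpy()
        sel = in_cond & gated
        n_gated = int(sel.sum())
        if n_gated < 2:
            raise ValueError(
                f"condition {cond!r} has {n_gated} gated cell(s); need >= 2"
            )
        r = norm_pla[sel] / norm_egfp[sel]
        ratios[cond] = r
        per_condition[cond] = ConditionStats(
            n_cells_total=int(in_cond.sum()),
            n_cells_gated=n_gated,
            median_pla=float(np.median(pla[sel])),
            median_egfp=float(np.median(egfp[sel])),
            mean_ratio=float(np.mean(r)),
            sd_ratio=float(np.std(r, ddof=1)),
        )

    wt, mut = ratios["wt"], ratios["mutant"]
    effect = per_condition["mutant"].mean_ratio / per_condition["wt"].mean_ratio

    f_stat = float(np.var(mut, ddof=1) / np.var(wt, ddof=1))
    f_cdf = stats.f.cdf(f_stat, len(mut) - 1, len(wt) - 1)
    f_p = float(2 * min(f_cdf, 1 - f_cdf))

    t_res = stats.ttest_ind(mut, wt, equal_var=False)
    return PlaResult(
        per_condition=per_condition,
        effect=float(effect),
        f_stat=f_stat,
        f_p=f_p,
        welch_t=float(t_res.statistic),
        welch_df=float(_welch_df(mut, wt)),
        welch_p=float(t_res.pvalue),
        egfp_gate=float(egfp_gate),
        gate_on=gate_on,
    )


def pooled_pla_summary(results: list[PlaResult], weights: str = "equal") -> dict:
    """Unweighted mean and SD of per-experiment effects (>=2 experiments)."""
    if weights != "equal":
        raise ValueError("only equal weighting is supported")
    if len(results) < 2:
        raise ValueError("need >= 2 experiments to pool")
    effects = np.array([r.effect for r in results], dtype=float)
    return {
        "n_experiments": len(effects),
        "mean_effect": float(np.mean(effects)),
        "sd_effect": float(np.std(effects, ddof=1)),
    }


__all__ = [
    "ConditionStats",
    "PlaResult",
    "pla_ratio_test",
    "pooled_pla_summary",
    "DEFAULT_EGFP_GATE",
]
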