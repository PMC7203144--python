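"""Score a query IP proteome's domain property against sheet/tubule
reference proteomes.

Each protein contributes one observation: its log2 fold change averaged
across antibody sets (and replicates).  Observations are grouped by
reference class (and, optionally, by user-supplied annotation sets such as
mitochondrion/Golgi/peroxisome gene lists) and compared by one-way ANOVA
followed by Tukey's HSD post test at family-wise alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .enrichment import FoldChangeTable, ReferenceProteome


@dataclass
class ClassStats:
    n: int
    mean_log2fc: float
    sd: float
    values: np.ndarray


@dataclass
class DomainScoreResult:
    comparison: str
    per_class: dict  # class label -> ClassStats
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame  # columns: group1, group2, mean_diff, p_adj, significant
    alpha: float = 0.05

    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.tukey[self.tukey["significant"]]
        return list(zip(sig["group1"], sig["group2"]))

    def pair(self, g1: str, g2: str) -> pd.Series:
        t = self.tukey
        m = ((t["group1"] == g1) & (t["group2"] == g2)) | (
            (t["group1"] == g2) & (t["group2"] == g1)
        )
        if not m.any():
            raise KeyError((g1, g2))
        return t[m].iloc[0]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "comparison": self.comparison,
                "class": label,
                "n": cs.n,
                "mean_log2fc": cs.mean_log2fc,
                "sd": cs.sd,
                "anova_F": self.anova_f,
                "anova_p": self.anova_p,
            }
            for label, cs in self.per_class.items()
        ]
        return pd.DataFrame(rows)


def _grouped_anova(
    groups: dict, comparison: str, alpha: float
) -> DomainScoreResult:
    """Shared machinery: drop undersized groups, run ANOVA + Tukey HSD."""
    kept: dict[str, np.ndarray] = {}
    for label, values in groups.items():
        values = np.asarray(values, dtype=float)
        values = values[np.isfinite(values)]
        if len(values) < 2:
            warnings.warn(
                f"class {label!r} has <2 covered proteins; dropped", stacklevel=3
            )
            continue
        kept[label] = values
    if len(kept) < 2:
        raise ValueError("fewer than 2 classes with >=2 covered proteins")

    labels = list(kept)
    f_stat, p_val = stats.f_oneway(*kept.values())

    endog = np.concatenate([kept[g] for g in labels])
    group_idx = np.concatenate([[g] * len(kept[g]) for g in labels])
    tk = pairwise_tukeyhsd(endog, group_idx, alpha=alpha)
    pairs = [
        (tk.groupsunique[i], tk.groupsunique[j])
        for i in range(len(tk.groupsunique))
        for j in range(i + 1, len(tk.groupsunique))
    ]
    tukey = pd.DataFrame(
        {
            "group1": [p[0] for p in pairs],
            "group2": [p[1] for p in pairs],
            "mean_diff": tk.meandiffs,
            "p_adj": tk.pvalues,
            "significant": tk.reject,
        }
    )
    per_class = {
        g: ClassStats(
            n=len(v),
            mean_log2fc=float(np.mean(v)),
            sd=float(np.std(v, ddof=1)),
            values=v,
        )
        for g, v in kept.items()
    }
    return DomainScoreResult(
        comparison=comparison,
        per_class=per_class,
        anova_f=float(f_stat),
        anova_p=float(p_val),
        tukey=tukey,
        alpha=alpha,
    )


def score_domains(
    fc: FoldChangeTable,
    refs: list[ReferenceProteome],
    alpha: float = 0.05,
) -> DomainScoreResult:
    """Group a comparison's per-protein averaged log2FCs by reference class
    and test class differences (one-way ANOVA + Tukey HSD)."""
    means = fc.per_protein_mean()
    groups = {
        ref.name: means.reindex(sorted(ref.members)).to_numpy() for ref in refs
    }
    comparison = f"{fc.comparison[0]}/{fc.comparison[1]}"
    return _grouped_anova(groups, comparison, alpha)


def class_shift_test(
    fc_mut: FoldChangeTable,
    refs: list[ReferenceProteome],
    extra_sets: dict | None = None,
    fc_wt: FoldChangeTable | None = None,
    alpha: float = 0.05,
) -> DomainScoreResult:
    """Test for a class-specific shift in a mutant-vs-wt comparison.

    Groups the mutant/wt log2FCs by reference class and by any user-supplied
    annotation sets (label -> accession/gene set), then runs ANOVA + Tukey.
    With ``fc_wt`` given, the four-group variant is run instead: both
    comparisons' values grouped as ``<bait>:<class>``.
    """
    extra_sets = extra_sets or {}

    def groups_for(fc: FoldChangeTable, prefix: str = "") -> dict:
        means = fc.per_protein_mean()
        genes = dict(zip(fc.data["accession"], fc.data["gene"]))
        out = {}
        for ref in refs:
            out[prefix + ref.name] = means.reindex(sorted(ref.members)).to_numpy()
        for label, ids in extra_sets.items():
            ids = set(ids)
            accs = sorted(
                a for a in means.index if a in ids or genes.get(a) in ids
            )
            out[prefix + label] = means.reindex(accs).to_numpy()
        return out

    if fc_wt is None:
        groups = groups_for(fc_mut)
        comparison = f"{fc_mut.comparison[0]}/{fc_mut.comparison[1]}"
    else:
        groups = {}
        groups.update(groups_for(fc_wt, prefix=f"{fc_wt.comparison[0]}:"))
        groups.update(groups_for(fc_mut, prefix=f"{fc_mut.comparison[0]}:"))
        comparison = (
            f"{fc_wt.comparison[0]}/{fc_wt.comparison[1]} vs "
            f"{fc_mut.comparison[0]}/{fc_mut.comparison[1]}"
        )
    return _grouped_anova(groups, comparison, alpha)


__all__ = [
    "ClassStats",
    "DomainScoreResult",
    "score_domains",
    "class_shift_test",
]
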