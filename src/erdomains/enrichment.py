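"""Normalization, non-specific/low-abundance exclusion, fold changes and
replicate-intersected enrichment calls.

The comparative IP analysis runs: normalize the abundance matrix (median
centering and/or bait-protein scaling), exclude proteins captured in the
tag-only control IPs and proteins of very low abundance, compute per-antibody
log2 fold changes between the two baits, and call a protein domain-enriched
only when it clears the fold-change threshold in every antibody set of every
biological replicate.  Missing values are never imputed: a protein missing on
either side of a ratio gets a missing fold change and cannot be called.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tables import AbundanceMatrix


@dataclass
class NormalizationSpec:
    """How to normalize and filter an IP abundance matrix.

    ``order`` fixes the sequence of normalization steps; each step only runs
    if enabled (``median_center``) or applicable (``bait_accessions``
    non-empty).  ``min_control_fraction`` is the fraction of a protein's IP
    abundance tolerated in the matched control before the protein is declared
    non-specific.
    """

    median_center: bool = True
    bait_accessions: dict = field(default_factory=dict)  # bait -> accession
    low_abundance_quantile: float = 0.05
    min_control_fraction: float = 0.5
    order: tuple[str, ...] = ("median", "bait")
    #: which proteins define each sample's median: "auto" uses the proteins
    #: detected in the tag-only control IPs (bait-invariant background
    #: binding) whenever controls are present, falling back to all proteins;
    #: "all" always uses every protein.  Normalizing on the background set
    #: avoids the composition bias that arises when a sizable specifically
    #: captured class shifts one bait's bulk abundance distribution.
    median_scope: str = "auto"

    def __post_init__(self):
        if not (0 <= self.low_abundance_quantile < 1):
            raise ValueError("low_abundance_quantile must be in [0, 1)")
        if self.min_control_fraction < 0:
            raise ValueError("min_control_fraction must be >= 0")
        unknown = set(self.order) - {"median", "bait"}
        if unknown:
            raise ValueError(f"unknown normalization steps: {sorted(unknown)}")
        if self.median_scope not in ("auto", "all"):
            raise ValueError("median_scope must be 'auto' or 'all'")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def _median_center(m: AbundanceMatrix, scope: str = "auto") -> None:
    rows = np.ones(len(m.proteins), dtype=bool)
    scope_used = "all"
    if scope == "auto":
        ctrl_cols = [j for j, s in enumerate(m.samples) if s.is_control]
        if ctrl_cols:
            ctrl = m.values[:, ctrl_cols]
            detected = np.any(np.isfinite(ctrl) & (ctrl > 0), axis=1)
            if detected.sum() >= 10:  # enough background proteins to anchor on
                rows = detected
                scope_used = "control_detected"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        col_medians = np.nanmedian(m.values[rows], axis=0)
    if np.any(~np.isfinite(col_medians)) or np.any(col_medians <= 0):
        raise ValueError("cannot median-center: a sample has no positive values")
    grand = np.median(col_medians)
    m.values *= grand / col_medians[None, :]
    m.log.append(f"normalize:median(scope={scope_used})")


def _bait_center(m: AbundanceMatrix, spec: NormalizationSpec) -> None:
    idx_cols = []
    bait_abund = []
    for j, s in enumerate(m.samples):
        if s.is_control:
            continue
        acc = spec.bait_accessions.get(s.bait)
        if acc is None:
            raise ValueError(f"no bait accession configured for bait {s.bait!r}")
        try:
            i = m.protein_index(acc)
        except KeyError:
            raise ValueError(
                f"bait accession {acc!r} absent from matrix; cannot bait-normalize"
            ) from None
        a = m.values[i, j]
        if not np.isfinite(a) or a <= 0:
            raise ValueError(
                f"bait protein {acc!r} missing in its own IP sample "
                f"{s.sample_id!r}; cannot bait-normalize"
            )
        idx_cols.append(j)
        bait_abund.append(a)
    bait_abund = np.asarray(bait_abund)
    target = bait_abund.mean()  # across-sample mean bait abundance
    for j, a in zip(idx_cols, bait_abund):
        m.values[:, j] *= target / a
    m.log.append("normalize:bait")


def normalize(matrix: AbundanceMatrix, spec: NormalizationSpec) -> AbundanceMatrix:
    """Scale each sample per ``spec``; the step order is recorded in the log.

    The median step scales every sample so its median non-missing abundance
    (computed over the control-detected background proteins when controls are
    present, see ``NormalizationSpec.median_scope``) equals the grand median
    (median of per-sample medians); the bait step then scales each
    non-control sample so its captured bait-protein abundance equals the
    across-sample mean bait abundance.
    """
    m = matrix.copy()
    for step in spec.order:
        if step == "median" and spec.median_center:
            _median_center(m, spec.median_scope)
        elif step == "bait" and spec.bait_accessions:
            _bait_center(m, spec)
    return m


# ---------------------------------------------------------------------------
# Non-specific / low-abundance exclusion
# ---------------------------------------------------------------------------

def _matched_control(m: AbundanceMatrix, sample) -> int:
    """Column index of the control matched to a sample (tag+antibody, same
    replicate preferred)."""
    exact = m.samples_where(
        is_control=True, tag=sample.tag, antibody=sample.antibody,
        replicate=sample.replicate,
    )
    if exact:
        return exact[0]
    loose = m.samples_where(is_control=True, tag=sample.tag, antibody=sample.antibody)
    if loose:
        return loose[0]
    raise ValueError(
        f"no control sample matches (tag={sample.tag}, antibody={sample.antibody})"
    )


def exclude_nonspecific(
    matrix: AbundanceMatrix, spec: NormalizationSpec
) -> AbundanceMatrix:
    """Drop non-specifically captured and low-abundance proteins.

    A protein is non-specific if, in any IP/control comparison, the matched
    tag-only control carries at least ``min_control_fraction`` of the IP
    abundance (or the protein is present in the control but absent from the
    IP).  A protein is low-abundance if its best IP measurement falls below
    the ``low_abundance_quantile`` of the pooled IP abundance distribution.
    """
    ip_cols = [j for j, s in enumerate(matrix.samples) if not s.is_control]
    ctrl_cols = [j for j, s in enumerate(matrix.samples) if s.is_control]
    if not ctrl_cols:
        raise ValueError("no control samples in matrix; cannot exclude non-specific")

    n = len(matrix.proteins)
    nonspecific = np.zeros(n, dtype=bool)
    for j in ip_cols:
        cj = _matched_control(matrix, matrix.samples[j])
        ip = matrix.values[:, j]
        ctrl = matrix.values[:, cj]
        ctrl_present = np.isfinite(ctrl) & (ctrl > 0)
        ip_absent = ~np.isfinite(ip)
        with np.errstate(invalid="ignore"):
            high_ctrl = ctrl_present & (
                ip_absent | (ctrl >= spec.min_control_fraction * ip)
            )
        nonspecific |= high_ctrl

    ip_vals = matrix.values[:, ip_cols]
    low = np.zeros(n, dtype=bool)
    if spec.low_abundance_quantile > 0:
        pooled = ip_vals[np.isfinite(ip_vals)]
        if pooled.size:
            thresh = np.quantile(pooled, spec.low_abundance_quantile)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
                best = np.nanmax(ip_vals, axis=1)
            low = ~np.isfinite(best) | (best < thresh)

    keep = ~(nonspecific | low)
    out = matrix.subset_proteins(keep)
    out.log.append(
        f"exclude_nonspecific: removed {int(nonspecific.sum())} control-positive "
        f"and {int((low & ~nonspecific).sum())} low-abundance proteins"
    )
    if len(out.proteins) == 0:
        raise ValueError("all proteins excluded; check control/abundance filters")
    return out


# ---------------------------------------------------------------------------
# Fold changes
# ---------------------------------------------------------------------------

@dataclass
class FoldChangeTable:
    """Per-protein log2 fold changes for one bait-pair comparison.

    ``data`` has columns ``accession``, ``gene``, ``replicate`` and one
    ``log2fc_<antibody>`` column per antibody set.
    """

    comparison: tuple[str, str]  # (numerator bait, denominator bait)
    antibodies: tuple[str, ...]
    data: pd.DataFrame

    @property
    def fc_columns(self) -> list[str]:
        return [f"log2fc_{ab}" for ab in self.antibodies]

    def per_protein_mean(self) -> pd.Series:
        """Mean log2FC per protein across antibody sets and replicates
        (missing values ignored; proteins with no finite value get NaN)."""
        df = self.data[["accession"] + self.fc_columns]
        grouped = df.set_index("accession")[self.fc_columns].stack(future_stack=True)
        return grouped.groupby(level=0).mean()

    def negated(self) -> "FoldChangeTable":
        data = self.data.copy()
        for col in self.fc_columns:
            data[col] = -data[col]
        return FoldChangeTable(
            comparison=(self.comparison[1], self.comparison[0]),
            antibodies=self.antibodies,
            data=data,
        )


def fold_changes(
    matrix: AbundanceMatrix, numerator: str, denominator: str
) -> FoldChangeTable:
    """log2(numerator-bait / denominator-bait) per antibody set and replicate.

    Zeros and missing values on either side yield a missing fold change (no
    imputation).  Antibodies measured for only one bait are skipped with a
    warning.
    """
    num_abs = {s.antibody for s in matrix.samples if s.bait == numerator}
    den_abs = {s.antibody for s in matrix.samples if s.bait == denominator}
    if not num_abs or not den_abs:
        raise ValueError(
            f"baits {numerator!r}/{denominator!r} not both present in matrix"
        )
    common = sorted(num_abs & den_abs)
    for ab in sorted(num_abs ^ den_abs):
        warnings.warn(
            f"antibody {ab!r} measured for only one bait; skipped", stacklevel=2
        )
    if not common:
        raise ValueError("no antibody set shared by both baits")

    reps = sorted(
        {s.replicate for s in matrix.samples if s.bait in (numerator, denominator)}
    )
    frames = []
    for rep in reps:
        block = matrix.proteins[["accession", "gene"]].copy()
        block["replicate"] = rep
        any_pair = False
        for ab in common:
            jn = matrix.samples_where(bait=numerator, antibody=ab, replicate=rep)
            jd = matrix.samples_where(bait=denominator, antibody=ab, replicate=rep)
            if not jn or not jd:
                block[f"log2fc_{ab}"] = np.nan
                continue
            any_pair = True
            a = matrix.values[:, jn[0]].copy()
            b = matrix.values[:, jd[0]].copy()
            a[a == 0] = np.nan
            b[b == 0] = np.nan
            with np.errstate(invalid="ignore", divide="ignore"):
                block[f"log2fc_{ab}"] = np.log2(a / b)
        if any_pair:
            frames.append(block)
    data = pd.concat(frames, ignore_index=True)
    return FoldChangeTable(
        comparison=(numerator, denominator), antibodies=tuple(common), data=data
    )


def fold_change_frame(fc: FoldChangeTable) -> pd.DataFrame:
    """Flat TSV-ready view of a FoldChangeTable."""
    df = fc.data.copy()
    df.insert(0, "comparison", f"{fc.comparison[0]}/{fc.comparison[1]}")
    return df


# ---------------------------------------------------------------------------
# Enrichment calls
# ---------------------------------------------------------------------------

@dataclass
class ReferenceProteome:
    """Replicate-intersected set of proteins called enriched for one domain."""

    name: str
    members: set
    provenance: pd.DataFrame  # per-member log2FCs in each antibody set/replicate

    def __post_init__(self):
        self.members = set(self.members)


def call_enriched(
    fcs, tau: float, side: str, name: str | None = None
) -> ReferenceProteome:
    """Call proteins enriched on one side of a bait-pair comparison.

    A protein is a member iff its signed log2FC meets the threshold
    (>= tau on the numerator side, <= -tau on the denominator side) in EVERY
    antibody set of EVERY replicate; a missing fold change fails the
    threshold.  ``fcs`` is one FoldChangeTable (replicates stacked in its
    ``replicate`` column) or a list of per-replicate tables.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if side not in ("numerator", "denominator"):
        raise ValueError("side must be 'numerator' or 'denominator'")
    tables = fcs if isinstance(fcs, (list, tuple)) else [fcs]
    if not tables:
        raise ValueError("need at least one FoldChangeTable")
    comparison = tables[0].comparison
    antibodies = tables[0].antibodies
    for t in tables[1:]:
        if t.comparison != comparison or t.antibodies != antibodies:
            raise ValueError("fold-change tables disagree on comparison/antibodies")

    data = pd.concat([t.data for t in tables], ignore_index=True)
    fc_cols = [f"log2fc_{ab}" for ab in antibodies]
    n_sets = data[["accession", "replicate"]].drop_duplicates().groupby(
        "accession"
    ).size() * len(fc_cols)

    stacked = data.melt(
        id_vars=["accession", "replicate"], value_vars=fc_cols, value_name="fc"
    )
    if side == "numerator":
        stacked["pass"] = stacked["fc"] >= tau
    else:
        stacked["pass"] = stacked["fc"] <= -tau
    stacked.loc[stacked["fc"].isna(), "pass"] = False
    passed = stacked.groupby("accession")["pass"].agg(["sum", "size"])
    members = set(passed.index[(passed["sum"] == passed["size"])])

    provenance = data[data["accession"].isin(members)].sort_values(
        ["accession", "replicate"], kind="mergesort"
    ).reset_index(drop=True)
    if name is None:
        name = comparison[0] if side == "numerator" else comparison[1]
    return ReferenceProteome(name=name, members=members, provenance=provenance)


def reference_frame(ref: ReferenceProteome) -> pd.DataFrame:
    df = ref.provenance.copy()
    df.insert(0, "reference", ref.name)
    return df


def reduced_set(fc: FoldChangeTable, cutoff: float = -0.5) -> set:
    """Accessions whose mean-across-antibody-sets log2FC is strictly below
    ``cutoff`` (mutant-as-numerator convention; default -0.5)."""
    means = fc.per_protein_mean()
    return set(means.index[means < cutoff])


def select_top_n(
    matrix: AbundanceMatrix, bait: str, n: int, subtract=frozenset()
) -> list[str]:
    """Gene list export for external PPI/annotation services.

    Proteins are ranked by mean normalized abundance across the bait's IP
    samples (ties broken by accession, lexicographically), the top ``n``
    taken, and the subtract set (accessions) removed after ranking.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cols = matrix.samples_where(bait=bait, is_control=False)
    if not cols:
        raise ValueError(f"no IP samples for bait {bait!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(matrix.values[:, cols], axis=1)
    df = pd.DataFrame(
        {
            "accession": matrix.proteins["accession"],
            "gene": matrix.proteins["gene"],
            "mean_abundance": means,
        }
    )
    df = df[np.isfinite(df["mean_abundance"])]
    df = df.sort_values(
        ["mean_abundance", "accession"], ascending=[False, True], kind="mergesort"
    )
    if n > len(df):
        warnings.warn(
            f"requested top {n} but only {len(df)} proteins available", stacklevel=2
        )
    top = df.head(n)
    top = top[~top["accession"].isin(set(subtract))]
    return top["gene"].tolist()


__all__ = [
    "NormalizationSpec",
    "FoldChangeTable",
    "ReferenceProteome",
    "normalize",
    "exclude_nonspecific",
    "fold_changes",
    "fold_change_frame",
    "call_enriched",
    "reference_frame",
    "reduced_set",
    "select_top_n",
]
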