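"""Synthetic inputs with planted ground truth for every pipeline stage.

Three generators mirror the three experimental inputs:

``simulate_ip_experiment``
    A two-bait x two-antibody x two-replicate immuno-isolation LFQ
    experiment with planted sheet / tubule / shared / background protein
    classes, bait-dependent capture, per-sample multiplicative antibody
    effects, lognormal measurement noise and rank-based low-abundance
    dropout.  Tag-only control IPs capture background proteins only.

``simulate_proteome``
    Random protein sequences with FFAT-like motifs (six-residue acidic
    tract followed by a canonical core) planted at recorded positions.

``simulate_pla``
    Two-condition per-cell (PLA, EGFP) intensity tables with a planted
    ratio reduction and unequal variances.

The generative model is multiplicative-lognormal throughout, which is the
standard error model for LFQ intensities and gives closed-form expected
fold changes: with noise, antibody effects and dropout switched off, the
log2 fold change of a planted class equals log2 of its capture ratio
bit-exactly whenever the capture multipliers are powers of two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tables import (
    AMINO_ACIDS,
    AbundanceMatrix,
    FastaRecord,
    PlaCellTable,
    ProteomeFasta,
    SampleMeta,
)

CLASSES = ("sheet", "tubule", "shared", "background")

#: canonical FFAT core planted by the proteome simulator (position 6 is a
#: wildcard in the consensus; the simulator draws it from non-proline
#: residues so the planted window scores exactly 0 under the default matrix)
CANONICAL_CORE_TEMPLATE = "EFFDA{x}E"
ACIDIC = "DE"


@dataclass
class SimConfig:
    """Study-design parameters of the simulated IP experiment.

    Defaults mirror the scale of the real study: ~200 sheet-specific and
    ~50 tubule-specific proteins among ~1500 total, two baits, two
    antibodies, two biological replicates, with tag-only controls.
    """

    seed: int
    n_sheet: int = 200
    n_tubule: int = 50
    n_shared: int = 0
    n_background: int = 1250
    baits: tuple[str, str] = ("Climp63", "DP1")
    tag: str = "mRFP"
    antibodies: tuple[str, ...] = ("3G5", "8D6")
    n_replicates: int = 2
    #: bait -> class -> relative capture efficiency
    capture: dict | None = None
    antibody_effect_sd: float = 0.2  # log2-scale per-sample IP-efficiency sd
    noise_sd: float = 0.3            # log2-scale residual measurement sd
    dropout_quantile: float = 0.02   # lowest fraction of expected values lost
    tubule_reduction: float = 1.0    # multiplier on mutant-bait tubule capture
    mutant_bait: str | None = None
    base_log2_mean: float = 20.0     # LFQ-style abundance scale (~1e6)
    base_log2_sd: float = 3.0
    bait_log2_abundance: float = 26.0  # bait protein: class-independent, high

    def __post_init__(self):
        for name in ("n_sheet", "n_tubule", "n_shared", "n_background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.antibody_effect_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not (0 <= self.dropout_quantile < 1):
            raise ValueError("dropout_quantile must be in [0, 1)")
        if not (0 < self.tubule_reduction <= 1):
            raise ValueError("tubule_reduction must be in (0, 1]")
        if self.capture is None:
            self.capture = default_capture(self.baits)
        for bait in self.baits:
            if bait not in self.capture:
                raise ValueError(f"no capture efficiencies for bait {bait!r}")
            if any(v < 0 for v in self.capture[bait].values()):
                raise ValueError("capture multipliers must be >= 0")


def default_capture(baits: tuple[str, str]) -> dict:
    """4:1 reciprocal sheet/tubule capture; shared and background symmetric."""
    b1, b2 = baits
    return {
        b1: {"sheet": 4.0, "tubule": 1.0, "shared": 2.0, "background": 1.0},
        b2: {"sheet": 1.0, "tubule": 4.0, "shared": 2.0, "background": 1.0},
    }


def sheet_tubule_config(seed: int, **overrides) -> SimConfig:
    """Default sheet-vs-tubule reference experiment (Climp63 vs DP1, mRFP)."""
    return SimConfig(seed=seed, **overrides)


def vapb_config(seed: int, tubule_reduction: float = 1.0, **overrides) -> SimConfig:
    """Mutant-vs-wild-type experiment: two EGFP-VAPB baits with equal
    (intermediate) sheet/tubule capture; the mutant bait's tubule capture is
    scaled by ``tubule_reduction``."""
    baits = ("VAPB-wt", "VAPB-P56S")
    capture = {
        bait: {"sheet": 2.0, "tubule": 2.0, "shared": 2.0, "background": 1.0}
        for bait in baits
    }
    defaults = dict(
        baits=baits,
        tag="EGFP",
        antibodies=("598", "D153"),
        capture=capture,
        mutant_bait="VAPB-P56S",
        tubule_reduction=tubule_reduction,
    )
    defaults.update(overrides)
    return SimConfig(seed=seed, **defaults)


@dataclass
class GroundTruth:
    """Planted truth for parameter-recovery tests."""

    class_of: dict = field(default_factory=dict)       # accession -> class
    planted_motifs: dict = field(default_factory=dict)  # seq_id -> [1-based starts]
    pla_effect: float | None = None

    def members(self, cls: str) -> set:
        return {acc for acc, c in self.class_of.items() if c == cls}


def bait_accession(bait: str) -> str:
    return f"BAIT_{bait}"


# ---------------------------------------------------------------------------
# IP experiment
# ---------------------------------------------------------------------------

def simulate_ip_experiment(cfg: SimConfig) -> tuple[AbundanceMatrix, GroundTruth]:
    """Simulate the full IP design of ``cfg``; deterministic given its seed.

    Abundance of protein *i* in sample *s* is
    ``base_i * capture[bait_s][class_i] * antibody_mult_s * 2**N(0, noise_sd)``.
    Control samples capture background proteins only (all planted classes are
    absent, i.e. missing).  The lowest ``dropout_quantile`` fraction of
    positive expected values is set missing.  Each bait's own tagged protein
    is included at class-independent high abundance so bait normalization can
    be exercised.
    """
    counts = [cfg.n_sheet, cfg.n_tubule, cfg.n_shared, cfg.n_background]
    if sum(counts) == 0:
        raise ValueError("all class counts are zero; nothing to simulate")
    rng = np.random.default_rng(cfg.seed)

    classes: list[str] = []
    accs: list[str] = []
    prefixes = {"sheet": "SHT", "tubule": "TUB", "shared": "SHD", "background": "BG"}
    for cls, n in zip(CLASSES, counts):
        for k in range(n):
            classes.append(cls)
            accs.append(f"{prefixes[cls]}{k + 1:04d}")
    n_planted = len(accs)
    # bait proteins appended last
    for bait in cfg.baits:
        classes.append("bait")
        accs.append(bait_accession(bait))

    base = np.empty(len(accs))
    base[:n_planted] = np.exp2(
        rng.normal(cfg.base_log2_mean, cfg.base_log2_sd, size=n_planted)
    )
    base[n_planted:] = np.exp2(cfg.bait_log2_abundance)

    samples: list[SampleMeta] = []
    for bait in cfg.baits:
        for ab in cfg.antibodies:
            for rep in range(1, cfg.n_replicates + 1):
                samples.append(
                    SampleMeta(f"{bait}.{ab}.r{rep}", bait, cfg.tag, ab, rep, False)
                )
    for ab in cfg.antibodies:
        for rep in range(1, cfg.n_replicates + 1):
            samples.append(
                SampleMeta(f"ctrl.{ab}.r{rep}", "tag-only", cfg.tag, ab, rep, True)
            )

    # per-sample multiplicative antibody/IP-efficiency effect
    ab_mult = np.exp2(rng.normal(0.0, cfg.antibody_effect_sd, size=len(samples)))

    capture = np.zeros((len(accs), len(samples)))
    for j, s in enumerate(samples):
        for i, cls in enumerate(classes):
            if s.is_control:
                eff = 1.0 if cls == "background" else 0.0
            elif cls == "bait":
                eff = 1.0 if accs[i] == bait_accession(s.bait) else 0.0
            else:
                eff = cfg.capture[s.bait][cls]
                if cls == "tubule" and s.bait == cfg.mutant_bait:
                    eff = eff * cfg.tubule_reduction
            capture[i, j] = eff

    expected = base[:, None] * capture * ab_mult[None, :]
    noise = np.exp2(rng.normal(0.0, cfg.noise_sd, size=expected.shape))
    values = expected * noise
    values[capture == 0] = np.nan  # not captured at all -> absent

    if cfg.dropout_quantile > 0:
        positive = expected[capture > 0]
        thresh = np.quantile(positive, cfg.dropout_quantile)
        values[(capture > 0) & (expected <= thresh)] = np.nan

    proteins = pd.DataFrame(
        {
            "accession": accs,
            "gene": [a.capitalize() for a in accs],
            "description": [f"simulated {c} protein" for c in classes],
        }
    )
    matrix = AbundanceMatrix(
        proteins=proteins,
        samples=samples,
        values=values,
        log=[f"simulate_ip_experiment(seed={cfg.seed})"],
    )
    truth = GroundTruth(class_of=dict(zip(accs, classes)))
    return matrix, truth


def classification_metrics(called, truth: GroundTruth, cls: str) -> tuple[float, float]:
    """(sensitivity, precision) of a called member set against a planted class."""
    called = set(called)
    positives = truth.members(cls)
    tp = len(called & positives)
    sensitivity = tp / len(positives) if positives else float("nan")
    precision = tp / len(called) if called else float("nan")
    return sensitivity, precision


# ---------------------------------------------------------------------------
# Proteome with planted FFAT-like motifs
# ---------------------------------------------------------------------------

def simulate_proteome(
    n_proteins: int,
    motif_rate: float,
    seed: int,
    genes: list[str] | None = None,
) -> tuple[ProteomeFasta, GroundTruth]:
    """Random protein sequences (length 200-1500) with, at rate
    ``motif_rate``, one planted 13-mer FFAT-like motif (six acidic residues
    followed by a canonical core) at a recorded 1-based position.

    ``genes`` optionally names the records (one per gene symbol), so that a
    simulated proteome can be matched to a simulated IP experiment.
    """
    if not (0 <= motif_rate <= 1):
        raise ValueError("motif_rate must be in [0, 1]")
    if genes is not None:
        n_proteins = len(genes)
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    non_proline = [r for r in AMINO_ACIDS if r != "P"]

    records = []
    planted: dict[str, list[int]] = {}
    for i in range(n_proteins):
        gene = genes[i] if genes is not None else f"G{i + 1:04d}"
        seq_id = f"{gene}.p1" if genes is not None else f"P{i + 1:04d}"
        length = int(rng.integers(200, 1501))
        seq = rng.choice(aa, size=length)
        if rng.random() < motif_rate:
            pos0 = int(rng.integers(0, length - 12))
            tract = rng.choice(list(ACIDIC), size=6)
            core = CANONICAL_CORE_TEMPLATE.format(x=rng.choice(non_proline))
            seq[pos0 : pos0 + 6] = tract
            seq[pos0 + 6 : pos0 + 13] = list(core)
            planted[seq_id] = [pos0 + 1]
        records.append(FastaRecord(seq_id=seq_id, gene=gene, sequence="".join(seq)))
    return ProteomeFasta(records), GroundTruth(planted_motifs=planted)


# ---------------------------------------------------------------------------
# PLA per-cell tables
# ---------------------------------------------------------------------------

def _lognormal_from_moments(rng, mean: float, var: float, size: int) -> np.ndarray:
    """Lognormal draws with the given arithmetic mean and variance."""
    sigma2 = np.log1p(var / mean**2)
    mu = np.log(mean) - sigma2 / 2.0
    return np.exp(rng.normal(mu, np.sqrt(sigma2), size=size))


#: baseline per-cell PLA/EGFP ratio distribution of the wt condition:
#: mean 0.5 with 30% coefficient of variation
WT_RATIO_MEAN = 0.5
WT_RATIO_CV = 0.3
#: EGFP expression: lognormal with median 20000 (well above the 5000 gate)
EGFP_LOG_MEDIAN = np.log(20000.0)
EGFP_LOG_SD = 0.5


def simulate_pla(
    n_cells_per_condition: int,
    effect: float,
    var_ratio: float,
    seed: int,
) -> PlaCellTable:
    """Two-condition per-cell intensity table with a planted ratio reduction.

    Per-cell EGFP intensities are lognormal with mode well above the default
    gating threshold; PLA intensity is a cell-specific ratio times EGFP.  The
    mutant condition's mean ratio is ``effect`` times the wt mean ratio and
    its ratio variance is scaled by ``var_ratio``.
    """
    if n_cells_per_condition < 2:
        raise ValueError("need >= 2 cells per condition")
    if not (0 < effect <= 1):
        raise ValueError("effect must be in (0, 1]")
    if var_ratio <= 0:
        raise ValueError("var_ratio must be > 0")
    rng = np.random.default_rng(seed)
    n = n_cells_per_condition
    wt_var = (WT_RATIO_CV * WT_RATIO_MEAN) ** 2

    rows = []
    for cond, mean, var in (
        ("wt", WT_RATIO_MEAN, wt_var),
        ("mutant", effect * WT_RATIO_MEAN, var_ratio * wt_var),
    ):
        ratios = _lognormal_from_moments(rng, mean, var, n)
        egfp = np.exp(rng.normal(EGFP_LOG_MEDIAN, EGFP_LOG_SD, size=n))
        pla = ratios * egfp
        for k in range(n):
            rows.append(
                {
                    "cell_id": f"{cond}_{k + 1:04d}",
                    "condition": cond,
                    "pla": pla[k],
                    "egfp": egfp[k],
                }
            )
    return PlaCellTable(pd.DataFrame(rows))


__all__ = [
    "SimConfig",
    "GroundTruth",
    "default_capture",
    "sheet_tubule_config",
    "vapb_config",
    "bait_accession",
    "simulate_ip_experiment",
    "simulate_proteome",
    "simulate_pla",
    "classification_metrics",
    "CLASSES",
]
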