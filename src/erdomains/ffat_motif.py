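"""FFAT-like motif scanning with position-penalty scoring.

A FFAT ("two phenylalanines in an acidic tract") motif is the short linear
motif bound by the VAP MSP domain.  Scanning slides a 13-residue window over
each protein: window positions 1-6 are the upstream acidic tract, positions
7-13 the core (consensus E-F-F-D-A-x-E).  Every residue at every position
carries a non-negative penalty from a position-penalty matrix; the window
score is the sum (tract score + core score), lower is better, 0 is the
canonical motif in an ideal acidic context, and a total score strictly below
the cutoff (default 3) is a "strong" FFAT-like motif, following the
penalty-scoring scheme of Murphy & Levine's FFAT search.  The packaged
default matrix is the single source of truth for the penalties; alternative
matrices in the same TSV layout (rows = window positions 1-13, columns =
residues) can be supplied for sensitivity analysis.

Coordinates are 1-based inclusive; hits report both the 13-mer start and the
core start (13-mer start + 6).  The ambiguous residue X always receives the
position's maximum penalty (worst case).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .io_tables import AMINO_ACIDS, FastaRecord, ProteomeFasta

WINDOW = 13
TRACT_LEN = 6
CORE_LEN = 7
DEFAULT_STRONG_CUTOFF = 3.0

_DEFAULT_MATRIX_RESOURCE = "ffat_position_penalties.tsv"


@dataclass
class FfatScoreMatrix:
    """Position-penalty matrix for 13-mer FFAT-like windows.

    ``penalties`` has shape (13, 20) in the column order of ``residues``;
    rows 0-5 are the acidic-tract positions (acidity penalties already
    multiplied by their position weights), rows 6-12 the core positions.
    """

    penalties: np.ndarray
    residues: str = AMINO_ACIDS
    strong_cutoff: float = DEFAULT_STRONG_CUTOFF

    def __post_init__(self):
        self.penalties = np.asarray(self.penalties, dtype=float)
        if self.penalties.shape != (WINDOW, len(self.residues)):
            raise ValueError(
                f"penalty matrix must be {WINDOW} x {len(self.residues)}, "
                f"got {self.penalties.shape}"
            )
        if not np.all(np.isfinite(self.penalties)):
            raise ValueError("penalties must be finite")
        if np.any(self.penalties < 0):
            raise ValueError("penalties must be >= 0")
        if np.any(self.penalties.min(axis=1) > 0):
            raise ValueError("every position must have a zero-penalty residue")

    def penalty(self, position: int, residue: str) -> float:
        """Penalty for ``residue`` at 1-based window ``position`` (X = max)."""
        if residue == "X":
            return float(self.penalties[position - 1].max())
        return float(self.penalties[position - 1, self.residues.index(residue)])

    def lookup_table(self) -> np.ndarray:
        """(13, 21) table with the X (worst-case) column appended."""
        xcol = self.penalties.max(axis=1, keepdims=True)
        return np.hstack([self.penalties, xcol])


def load_matrix(path, strong_cutoff: float = DEFAULT_STRONG_CUTOFF) -> FfatScoreMatrix:
    """Load a penalty matrix TSV (rows = positions 1-13, columns = residues)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "position" not in df.columns:
        raise ValueError("matrix file lacks a 'position' column")
    df = df.sort_values("position")
    if list(df["position"]) != list(range(1, WINDOW + 1)):
        raise ValueError(f"matrix must define positions 1..{WINDOW}")
    missing = set(AMINO_ACIDS) - set(df.columns)
    if missing:
        raise ValueError(f"matrix lacks residue columns: {sorted(missing)}")
    penalties = df[list(AMINO_ACIDS)].to_numpy(dtype=float)
    return FfatScoreMatrix(penalties=penalties, strong_cutoff=strong_cutoff)


def default_matrix(strong_cutoff: float = DEFAULT_STRONG_CUTOFF) -> FfatScoreMatrix:
    ref = resources.files("erdomains.data") / _DEFAULT_MATRIX_RESOURCE
    with resources.as_file(ref) as path:
        return load_matrix(path, strong_cutoff=strong_cutoff)


@dataclass(frozen=True)
class FfatHit:
    """A scored 13-mer window (1-based inclusive coordinates)."""

    seq_id: str
    gene: str
    start: int        # 1-based start of the 13-mer window
    core_start: int   # 1-based start of the 7-residue core (= start + 6)
    window: str
    core: str
    core_score: float
    tract_score: float
    total_score: float


def hits_frame(hits: list[FfatHit]) -> pd.DataFrame:
    cols = [
        "seq_id", "gene", "start", "core_start", "window", "core",
        "core_score", "tract_score", "total_score",
    ]
    return pd.DataFrame([vars(h) for h in hits], columns=cols)


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

_CODE = np.full(128, -1, dtype=np.int64)
for _i, _r in enumerate(AMINO_ACIDS):
    _CODE[ord(_r)] = _i
_CODE[ord("X")] = len(AMINO_ACIDS)


def _window_scores(seq: str, table: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(tract_scores, core_scores) for every window start of ``seq``."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if np.any(codes < 0):
        bad = sorted(set(seq) - set(AMINO_ACIDS + "X"))
        raise ValueError(f"sequence contains invalid residues: {bad}")
    n_windows = len(seq) - WINDOW + 1
    tract = np.zeros(n_windows)
    core = np.zeros(n_windows)
    for k in range(TRACT_LEN):
        tract += table[k, codes[k : k + n_windows]]
    for k in range(TRACT_LEN, WINDOW):
        core += table[k, codes[k : k + n_windows]]
    return tract, core


def _sorted_hits(hits: list[FfatHit]) -> list[FfatHit]:
    return sorted(hits, key=lambda h: (h.total_score, h.seq_id, h.start))


def scan(
    proteome: ProteomeFasta,
    matrix: FfatScoreMatrix | None = None,
    report: str = "best_per_protein",
    cutoff: float | None = None,
) -> list[FfatHit]:
    """Score every 13-residue window of every sequence.

    ``report='best_per_protein'`` returns the minimum-scoring window per
    protein (earliest window on ties); ``report='all_below_cutoff'`` returns
    every window with total score strictly below ``cutoff`` (defaults to the
    matrix's strong cutoff).  Hits are sorted by (total score, seq_id,
    start).  Sequences shorter than 13 residues are skipped with a warning.
    """
    if report not in ("best_per_protein", "all_below_cutoff"):
        raise ValueError(f"unknown report mode {report!r}")
    if matrix is None:
        matrix = default_matrix()
    if cutoff is None:
        cutoff = matrix.strong_cutoff
    table = matrix.lookup_table()

    hits: list[FfatHit] = []

    def make_hit(rec: FastaRecord, i: int, tract: float, core: float) -> FfatHit:
        return FfatHit(
            seq_id=rec.seq_id,
            gene=rec.gene,
            start=i + 1,
            core_start=i + 1 + TRACT_LEN,
            window=rec.sequence[i : i + WINDOW],
            core=rec.sequence[i + TRACT_LEN : i + WINDOW],
            core_score=float(core),
            tract_score=float(tract),
            total_score=float(tract + core),
        )

    for rec in proteome:
        if len(rec.sequence) < WINDOW:
            warnings.warn(
                f"sequence {rec.seq_id!r} shorter than {WINDOW} residues; skipped",
                stacklevel=2,
            )
            continue
        tract, core = _window_scores(rec.sequence, table)
        total = tract + core
        if report == "best_per_protein":
            i = int(np.argmin(total))  # argmin takes the earliest on ties
            hits.append(make_hit(rec, i, tract[i], core[i]))
        else:
            for i in np.flatnonzero(total < cutoff):
                hits.append(make_hit(rec, int(i), tract[i], core[i]))
    return _sorted_hits(hits)


# ---------------------------------------------------------------------------
# Longest isoform per gene, reduced-set scan
# ---------------------------------------------------------------------------

def longest_per_gene(proteome: ProteomeFasta) -> ProteomeFasta:
    """Keep one record per gene symbol: the longest sequence, ties broken by
    lexicographically smallest seq_id.  First-occurrence gene order kept."""
    best: dict[str, FastaRecord] = {}
    order: list[str] = []
    for rec in proteome:
        cur = best.get(rec.gene)
        if cur is None:
            best[rec.gene] = rec
            order.append(rec.gene)
        # longer wins; equal length -> lexicographically smaller seq_id wins
        elif len(rec) > len(cur) or (len(rec) == len(cur) and rec.seq_id < cur.seq_id):
            best[rec.gene] = rec
    return ProteomeFasta([best[g] for g in order])


def scan_reduced_set(
    proteome: ProteomeFasta,
    reduced,
    matrix: FfatScoreMatrix | None = None,
    cutoff: float | None = None,
) -> list[FfatHit]:
    """Strong FFAT-like motifs among a reduced protein set.

    Restricts the proteome to the reduced accessions/genes, keeps the longest
    isoform per gene, scans with best-window-per-protein reporting, and
    returns hits with total score strictly below the cutoff.
    """
    if matrix is None:
        matrix = default_matrix()
    if cutoff is None:
        cutoff = matrix.strong_cutoff
    reduced = set(reduced)
    records = [r for r in proteome if r.seq_id in reduced or r.gene in reduced]
    found = {r.seq_id for r in records} | {r.gene for r in records}
    unmatched = reduced - found
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} reduced-set entries not found in proteome",
            stacklevel=2,
        )
    if not records:
        warnings.warn("reduced set has empty intersection with proteome", stacklevel=2)
        return []
    matched = ProteomeFasta(records)
    best = scan(longest_per_gene(matched), matrix, report="best_per_protein")
    return _sorted_hits([h for h in best if h.total_score < cutoff])


__all__ = [
    "FfatScoreMatrix",
    "FfatHit",
    "load_matrix",
    "default_matrix",
    "scan",
    "longest_per_gene",
    "scan_reduced_set",
    "hits_frame",
    "WINDOW",
    "DEFAULT_STRONG_CUTOFF",
]
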