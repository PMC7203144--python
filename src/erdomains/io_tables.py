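"""Tabular/sequence I/O and the shared data model for IP-proteomics tables.

The pipeline starts downstream of the mass-spec search engine: its inputs are
a protein x sample label-free-quantification (LFQ) abundance table exported as
TSV, a sample-metadata table describing each immunoprecipitation (bait, tag,
antibody, replicate, control flag), a proteome FASTA, and per-cell
fluorescence-intensity tables for proximity ligation assays.

Conventions
-----------
* Missing abundance is represented as NaN ("absent"), never as 0.  Zeros in
  the input are kept as 0 and treated as "low abundance" downstream.
* All tables are exchanged as TSV with missing values rendered as ``NA``;
  reading back a written table reproduces every value bit-exactly.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_TAGS = ("EGFP", "mRFP")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ALLOWED_RESIDUES = frozenset(AMINO_ACIDS + "X")

NA_REP = "NA"


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleMeta:
    """One IP sample: which bait was pulled down, with which antibody."""

    sample_id: str
    bait: str
    tag: str
    antibody: str
    replicate: int
    is_control: bool = False

    def __post_init__(self):
        if self.tag not in VALID_TAGS:
            raise ValueError(
                f"sample {self.sample_id!r}: tag must be one of {VALID_TAGS}, got {self.tag!r}"
            )
        if self.replicate < 1:
            raise ValueError(f"sample {self.sample_id!r}: replicate must be >= 1")


# ---------------------------------------------------------------------------
# Abundance matrix
# ---------------------------------------------------------------------------

@dataclass
class AbundanceMatrix:
    """Protein x sample LFQ abundances with per-sample IP metadata.

    ``proteins`` is a DataFrame with columns ``accession``, ``gene``,
    ``description``; ``values`` is a float array of shape
    ``(n_proteins, n_samples)`` with NaN for missing measurements.
    ``log`` records the processing steps applied so far.
    """

    proteins: pd.DataFrame
    samples: list[SampleMeta]
    values: np.ndarray
    log: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n_prot = len(self.proteins)
        if self.values.shape != (n_prot, len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{n_prot} proteins x {len(self.samples)} samples"
            )
        if n_prot == 0:
            raise ValueError("abundance matrix contains zero proteins")
        acc = self.proteins["accession"]
        if acc.duplicated().any():
            dups = acc[acc.duplicated()].tolist()
            raise ValueError(f"duplicate accessions in matrix: {dups[:5]}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_ids in metadata")
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                raise ValueError("abundances must be >= 0 or missing")
        self.proteins = self.proteins.reset_index(drop=True)

    # -- convenience accessors ---------------------------------------------

    @property
    def accessions(self) -> pd.Series:
        return self.proteins["accession"]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample_index(self, sample_id: str) -> int:
        for i, s in enumerate(self.samples):
            if s.sample_id == sample_id:
                return i
        raise KeyError(sample_id)

    def samples_where(self, **criteria) -> list[int]:
        """Column indices of samples matching all given metadata fields."""
        out = []
        for i, s in enumerate(self.samples):
            if all(getattr(s, k) == v for k, v in criteria.items()):
                out.append(i)
        return out

    def protein_index(self, accession: str) -> int:
        hits = np.flatnonzero(self.accessions.to_numpy() == accession)
        if hits.size == 0:
            raise KeyError(accession)
        return int(hits[0])

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(
            proteins=self.proteins.copy(),
            samples=list(self.samples),
            values=self.values.copy(),
            log=list(self.log),
        )

    def subset_proteins(self, keep: np.ndarray) -> "AbundanceMatrix":
        """New matrix restricted to a boolean/index row selection."""
        return AbundanceMatrix(
            proteins=self.proteins.loc[keep].reset_index(drop=True),
            samples=list(self.samples),
            values=self.values[keep],
            log=list(self.log),
        )

    def to_frame(self) -> pd.DataFrame:
        df = self.proteins.copy()
        for j, sid in enumerate(self.sample_ids):
            df[sid] = self.values[:, j]
        return df

    def validate_design(self) -> None:
        """Check that every non-control bait has a matched tag+antibody control."""
        controls = {(s.tag, s.antibody) for s in self.samples if s.is_control}
        for s in self.samples:
            if not s.is_control and (s.tag, s.antibody) not in controls:
                raise ValueError(
                    f"bait {s.bait!r} (tag {s.tag}, antibody {s.antibody}) "
                    "has no matching control sample"
                )


# ---------------------------------------------------------------------------
# Proteome FASTA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FastaRecord:
    seq_id: str
    gene: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProteomeFasta:
    records: list[FastaRecord]

    def __post_init__(self):
        if not self.records:
            raise ValueError("proteome contains no records")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, keep_ids) -> "ProteomeFasta":
        keep = set(keep_ids)
        return ProteomeFasta(
            [r for r in self.records if r.seq_id in keep or r.gene in keep]
        )


def _parse_gene_symbol(description: str, fallback: str) -> str:
    # Ensembl peptide headers carry "... gene_symbol:Vapb ..." tokens.
    for token in description.split():
        if token.startswith("gene_symbol:"):
            return token.split(":", 1)[1]
    return fallback


def read_fasta(path, id_policy: str = "first_token") -> ProteomeFasta:
    """Read a (possibly gzipped) proteome FASTA into validated records.

    Sequences are uppercased and trailing ``*`` stop characters stripped;
    residues other than the 20 standard amino acids plus X are rejected.
    """
    if id_policy not in ("first_token", "full_header"):
        raise ValueError(f"unknown id_policy {id_policy!r}")
    opener = gzip.open if str(path).endswith(".gz") else open
    records = []
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq_id = rec.description if id_policy == "full_header" else rec.id
            seq = str(rec.seq).upper().rstrip("*")
            bad = set(seq) - _ALLOWED_RESIDUES
            if bad:
                raise ValueError(
                    f"record {rec.id!r} contains non-amino-acid characters: "
                    f"{sorted(bad)}"
                )
            gene = _parse_gene_symbol(rec.description, fallback=rec.id)
            records.append(FastaRecord(seq_id=seq_id, gene=gene, sequence=seq))
    if not records:
        raise ValueError(f"FASTA file {path} contains no records")
    return ProteomeFasta(records)


def write_fasta(proteome: ProteomeFasta, path) -> None:
    with open(path, "w") as fh:
        for rec in proteome.records:
            fh.write(f">{rec.seq_id} gene_symbol:{rec.gene}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# PLA per-cell intensity table
# ---------------------------------------------------------------------------

PLA_CONDITIONS = ("wt", "mutant")


@dataclass
class PlaCellTable:
    """Per-cell (PLA intensity, EGFP intensity, condition) records."""

    cells: pd.DataFrame  # columns: cell_id, condition, pla, egfp

    def __post_init__(self):
        required = ["cell_id", "condition", "pla", "egfp"]
        missing = [c for c in required if c not in self.cells.columns]
        if missing:
            raise ValueError(f"per-cell table lacks columns: {missing}")
        self.cells = self.cells.reset_index(drop=True)
        bad_cond = set(self.cells["condition"]) - set(PLA_CONDITIONS)
        if bad_cond:
            raise ValueError(f"unknown conditions {sorted(bad_cond)}; expected {PLA_CONDITIONS}")
        for cond in PLA_CONDITIONS:
            if not (self.cells["condition"] == cond).any():
                raise ValueError(f"condition {cond!r} absent from per-cell table")
        for col in ("pla", "egfp"):
            vals = self.cells[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"non-finite {col} intensities")
            if np.any(vals < 0):
                raise ValueError(f"negative {col} intensities")


def read_pla_table(path) -> PlaCellTable:
    df = pd.read_csv(
        path, sep="\t", na_values=[NA_REP], keep_default_na=False,
        float_precision="round_trip",
    )
    return PlaCellTable(df)


# ---------------------------------------------------------------------------
# Abundance table reader / generic result writer
# ---------------------------------------------------------------------------

def _read_sample_meta(meta_path) -> list[SampleMeta]:
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str})
    required = ["sample_id", "bait", "tag", "antibody", "replicate", "is_control"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata lacks columns: {missing}")
    samples = []
    for row in meta.itertuples(index=False):
        is_ctrl = row.is_control
        if isinstance(is_ctrl, str):
            is_ctrl = is_ctrl.strip().lower() in ("true", "1", "yes")
        samples.append(
            SampleMeta(
                sample_id=str(row.sample_id),
                bait=str(row.bait),
                tag=str(row.tag),
                antibody=str(row.antibody),
                replicate=int(row.replicate),
                is_control=bool(is_ctrl),
            )
        )
    return samples


def read_abundance_table(path, meta_path) -> AbundanceMatrix:
    """Read a TSV abundance matrix plus its sample-metadata TSV.

    The abundance TSV needs an ``accession`` column (``gene`` and
    ``description`` are optional) and one numeric column per ``sample_id``
    listed in the metadata.  Unparseable numeric cells become missing;
    duplicate accessions are dropped keep-first with a warning.
    """
    samples = _read_sample_meta(meta_path)
    df = pd.read_csv(path, sep="\t", na_values=[NA_REP], keep_default_na=False,
                     dtype=str)
    if "accession" not in df.columns:
        raise ValueError("abundance table lacks an 'accession' column")
    for s in samples:
        if s.sample_id not in df.columns:
            raise ValueError(
                f"sample {s.sample_id!r} listed in metadata is missing from "
                f"the abundance table"
            )
    if df["accession"].duplicated().any():
        n_dup = int(df["accession"].duplicated().sum())
        warnings.warn(
            f"{n_dup} duplicate accession(s) in abundance table; keeping first",
            stacklevel=2,
        )
        df = df.loc[~df["accession"].duplicated()].reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("abundance table contains zero proteins")
    proteins = pd.DataFrame(
        {
            "accession": df["accession"],
            "gene": df.get("gene", df["accession"]),
            "description": df.get("description", pd.Series([""] * len(df))),
        }
    )
    proteins["gene"] = proteins["gene"].fillna(proteins["accession"])
    proteins["description"] = proteins["description"].fillna("")
    values = np.column_stack(
        [pd.to_numeric(df[s.sample_id], errors="coerce").to_numpy(dtype=float)
         for s in samples]
    )
    return AbundanceMatrix(proteins=proteins, samples=samples, values=values)


def write_abundance_table(matrix: AbundanceMatrix, path, meta_path=None) -> None:
    write_results(matrix.to_frame(), path)
    if meta_path is not None:
        meta = pd.DataFrame(
            [
                {
                    "sample_id": s.sample_id,
                    "bait": s.bait,
                    "tag": s.tag,
                    "antibody": s.antibody,
                    "replicate": s.replicate,
                    "is_control": s.is_control,
                }
                for s in matrix.samples
            ]
        )
        write_results(meta, meta_path)


def write_results(table: pd.DataFrame, path) -> None:
    """Write any result table as TSV: deterministic column order, NA for
    missing.  ``read_results(write_results(x)) == x`` bit-exactly (pandas
    writes shortest round-tripping float representations)."""
    if not isinstance(table, pd.DataFrame):
        raise TypeError("write_results expects a pandas DataFrame")
    table.to_csv(path, sep="\t", na_rep=NA_REP, index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", na_values=[NA_REP], keep_default_na=False,
        float_precision="round_trip",
    )


__all__ = [
    "SampleMeta",
    "AbundanceMatrix",
    "FastaRecord",
    "ProteomeFasta",
    "PlaCellTable",
    "read_abundance_table",
    "write_abundance_table",
    "read_fasta",
    "write_fasta",
    "read_pla_table",
    "write_results",
    "read_results",
    "AMINO_ACIDS",
]
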