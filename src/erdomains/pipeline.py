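"""End-to-end orchestration: simulate (or load) -> normalize -> exclude ->
fold changes -> enrichment calls -> domain scoring -> reduced set -> FFAT
scan -> PLA test, with every intermediate table and a parameter manifest
written to a result directory.

All randomness flows from the single config seed; rerunning with the same
config and seed produces byte-identical outputs (no timestamps are written).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from . import __version__
from .domain_scoring import class_shift_test
from .enrichment import (
    NormalizationSpec,
    call_enriched,
    exclude_nonspecific,
    fold_change_frame,
    fold_changes,
    normalize,
    reduced_set,
    reference_frame,
    select_top_n,
)
from .ffat_motif import default_matrix, hits_frame, load_matrix, scan_reduced_set
from .io_tables import (
    read_abundance_table,
    read_fasta,
    read_pla_table,
    write_abundance_table,
    write_fasta,
    write_results,
)
from .pla_stats import pla_ratio_test
from .synthetic_data import (
    sheet_tubule_config,
    simulate_ip_experiment,
    simulate_pla,
    simulate_proteome,
    vapb_config,
)

import pandas as pd


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name for non-zero-exit reporting."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Every parameter of a full run; serialized into the manifest."""

    seed: int = 0
    # demo mode: generate all inputs; otherwise the four input paths are used
    simulate: bool = True
    domain_abundance: str | None = None
    domain_meta: str | None = None
    query_abundance: str | None = None
    query_meta: str | None = None
    fasta: str | None = None
    pla_cells: str | None = None
    # analysis parameters
    median_center: bool = True
    bait_normalize: bool = False
    norm_order: tuple[str, ...] = ("median", "bait")
    low_abundance_quantile: float = 0.05
    min_control_fraction: float = 0.5
    tau: float = 1.0
    reduced_cutoff: float = -0.5
    ffat_matrix: str | None = None  # None -> packaged default
    ffat_cutoff: float = 3.0
    pla_gate: float = 5000.0
    pla_gate_on: str = "raw"
    top_n: int = 500
    # simulation parameters (demo mode)
    tubule_reduction: float = 0.5
    noise_sd: float = 0.3
    motif_rate: float = 0.05
    pla_effect: float = 0.55
    pla_var_ratio: float = 2.0
    pla_n_cells: int = 150

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "norm_order" in raw:
            raw["norm_order"] = tuple(raw["norm_order"])
        return cls(**raw)


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - reported with stage name
            raise PipelineError(name, exc) from exc

    return wrap


def run_full(config: RunConfig, outdir) -> Path:
    """Execute every stage and write results into ``outdir`` (created)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- inputs -----------------------------------------------------------
    def load_inputs():
        if config.simulate:
            cfg_dom = sheet_tubule_config(config.seed, noise_sd=config.noise_sd)
            m_dom, _ = simulate_ip_experiment(cfg_dom)
            cfg_q = vapb_config(
                config.seed + 1,
                tubule_reduction=config.tubule_reduction,
                noise_sd=config.noise_sd,
            )
            m_query, _ = simulate_ip_experiment(cfg_q)
            proteome, _ = simulate_proteome(
                0, config.motif_rate, config.seed + 2,
                genes=m_query.proteins["gene"].tolist(),
            )
            cells = simulate_pla(
                config.pla_n_cells, config.pla_effect, config.pla_var_ratio,
                config.seed + 3,
            )
            return m_dom, m_query, proteome, cells
        for name in ("domain_abundance", "domain_meta", "query_abundance",
                     "query_meta", "fasta", "pla_cells"):
            p = getattr(config, name)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"input {name!r} missing: {p}")
        m_dom = read_abundance_table(config.domain_abundance, config.domain_meta)
        m_query = read_abundance_table(config.query_abundance, config.query_meta)
        proteome = read_fasta(config.fasta)
        cells = read_pla_table(config.pla_cells)
        return m_dom, m_query, proteome, cells

    m_dom, m_query, proteome, cells = _stage("load-inputs")(load_inputs)
    write_abundance_table(m_dom, out / "abundance_domains.tsv",
                          out / "samples_domains.tsv")
    write_abundance_table(m_query, out / "abundance_query.tsv",
                          out / "samples_query.tsv")
    write_fasta(proteome, out / "proteome.fasta")
    write_results(cells.cells, out / "pla_cells.tsv")

    # ---- normalization + exclusion ---------------------------------------
    spec = NormalizationSpec(
        median_center=config.median_center,
        bait_accessions={},
        low_abundance_quantile=config.low_abundance_quantile,
        min_control_fraction=config.min_control_fraction,
        order=config.norm_order,
    )
    if config.bait_normalize:
        from .synthetic_data import bait_accession

        spec.bait_accessions = {
            s.bait: bait_accession(s.bait)
            for m in (m_dom, m_query)
            for s in m.samples
            if not s.is_control
        }

    n_dom = _stage("normalize")(normalize, m_dom, spec)
    n_query = _stage("normalize")(normalize, m_query, spec)
    f_dom = _stage("exclude-nonspecific")(exclude_nonspecific, n_dom, spec)
    f_query = _stage("exclude-nonspecific")(exclude_nonspecific, n_query, spec)
    write_abundance_table(f_dom, out / "abundance_domains_normalized.tsv")
    write_abundance_table(f_query, out / "abundance_query_normalized.tsv")

    # ---- fold changes + enrichment calls ---------------------------------
    dom_baits = [s.bait for s in m_dom.samples if not s.is_control]
    sheet_bait, tubule_bait = dom_baits[0], next(
        b for b in dom_baits if b != dom_baits[0]
    )
    fc_dom = _stage("fold-changes")(fold_changes, f_dom, sheet_bait, tubule_bait)
    write_results(fold_change_frame(fc_dom), out / "fold_changes_domains.tsv")

    q_baits = [s.bait for s in m_query.samples if not s.is_control]
    wt_bait = q_baits[0]
    mut_bait = next(b for b in q_baits if b != wt_bait)
    fc_query = _stage("fold-changes")(fold_changes, f_query, mut_bait, wt_bait)
    write_results(fold_change_frame(fc_query), out / "fold_changes_query.tsv")

    ref_sheet = _stage("call-enriched")(
        call_enriched, fc_dom, config.tau, "numerator", "sheet"
    )
    ref_tubule = _stage("call-enriched")(
        call_enriched, fc_dom, config.tau, "denominator", "tubule"
    )
    write_results(reference_frame(ref_sheet), out / "reference_sheet.tsv")
    write_results(reference_frame(ref_tubule), out / "reference_tubule.tsv")

    # ---- domain scoring on the mutant/wt comparison ----------------------
    score = _stage("score-domains")(
        class_shift_test, fc_query, [ref_sheet, ref_tubule]
    )
    write_results(score.to_frame(), out / "domain_scores.tsv")
    write_results(score.tukey, out / "domain_scores_tukey.tsv")

    # ---- reduced set + FFAT scan -----------------------------------------
    reduced = _stage("reduced-set")(reduced_set, fc_query, config.reduced_cutoff)
    gene_of = dict(zip(m_query.proteins["accession"], m_query.proteins["gene"]))
    reduced_genes = sorted(gene_of.get(a, a) for a in reduced)
    write_results(
        pd.DataFrame({"gene": reduced_genes}), out / "reduced_set.tsv"
    )

    matrix = (
        load_matrix(config.ffat_matrix, strong_cutoff=config.ffat_cutoff)
        if config.ffat_matrix
        else default_matrix(strong_cutoff=config.ffat_cutoff)
    )
    hits = _stage("ffat-scan")(
        scan_reduced_set, proteome, reduced_genes, matrix, config.ffat_cutoff
    )
    write_results(hits_frame(hits), out / "ffat_hits.tsv")

    # ---- PPI gene-list export --------------------------------------------
    ppi_genes = _stage("top-n")(
        select_top_n, f_dom, sheet_bait, min(config.top_n, len(f_dom.proteins)),
        ref_tubule.members,
    )
    write_results(pd.DataFrame({"gene": ppi_genes}), out / "ppi_gene_list.tsv")

    # ---- PLA --------------------------------------------------------------
    pla = _stage("pla-test")(
        pla_ratio_test, cells, config.pla_gate, config.pla_gate_on
    )
    write_results(pla.to_frame(), out / "pla_result.tsv")

    # ---- manifest ---------------------------------------------------------
    manifest = {
        "version": __version__,
        "parameters": asdict(config),
        "normalization_log": f_dom.log,
        "n_reference_sheet": len(ref_sheet.members),
        "n_reference_tubule": len(ref_tubule.members),
        "n_reduced": len(reduced),
        "n_strong_ffat": len(hits),
        "pla_effect": pla.effect,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=list) + "\n"
    )
    return out


__all__ = ["RunConfig", "PipelineError", "run_full"]
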