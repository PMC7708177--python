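"""End-to-end orchestration: counts -> TPM -> DE -> D/A -> summaries.

`run_heterosis_analysis` drives the full triad analysis from a single
config: per-triad differential tests against each parent, the scaled union,
D/A classification with induced/repressed tallies, cross-triad Venn
regions and family pattern tables, plus optional degradome, enrichment and
qPCR stages when their inputs are configured.  Every stage logs one line
(parameters and row counts) to ``run.log``, input files are checksummed,
and a machine-readable ``summary.json`` ties the numbers together.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import degradome as deg
from . import enrichment as enr
from .expression import differential_test, scaled_union, tpm_normalize
from .heterosis import (
    classify_triad_table,
    cross_hybrid_overlap,
    family_of,
    family_pattern_table,
    format_family_table,
    tally_direction,
)
from .io import TriadDesign, md5sum, read_annotation, read_counts, read_ct_table, read_fasta


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Malformed or inconsistent input data (CLI exit code 3)."""


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    Required inputs are the counts matrix and the triad design; the
    degradome, enrichment and qPCR stages run only when their file inputs
    are set.  Thresholds default to the conventional values: P < 0.01 with
    |log2FC| > 1 for DE, D/A classes cut at +/-0.5 and +/-2, duplex score
    <= 7 for degradome sites, P < 0.05 for enrichment.
    """

    counts: str
    design: str
    out_dir: str = "out"
    alpha: float = 0.01
    lfc_threshold: float = 1.0
    pseudocount: float = 1.0
    ttest: str = "student"
    da_epsilon: float = 1e-9
    degradome_reads: str | None = None
    transcripts: str | None = None
    mature_mirnas: str | None = None
    max_duplex_score: float = 7.0
    min_site_reads: int = 1
    annotation: str | None = None
    target_genes: str | None = None
    background_genes: str | None = None
    enrichment_alpha: float = 0.05
    ct_table: str | None = None
    calibrator: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)

    def validate(self) -> None:
        for name in ("counts", "design"):
            value = getattr(self, name)
            if value is None or not Path(value).exists():
                raise ConfigError(f"required input {name!r} missing or not found: {value!r}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.lfc_threshold < 0 or self.pseudocount < 0:
            raise ConfigError("lfc_threshold and pseudocount must be non-negative")
        if self.ttest not in ("student", "welch"):
            raise ConfigError(f"ttest must be 'student' or 'welch', got {self.ttest!r}")
        degr = (self.degradome_reads, self.transcripts, self.mature_mirnas)
        if any(degr) and not all(degr):
            raise ConfigError(
                "degradome stage needs degradome_reads, transcripts and mature_mirnas together"
            )
        enrich = (self.annotation, self.target_genes, self.background_genes)
        if any(enrich) and not all(enrich):
            raise ConfigError(
                "enrichment stage needs annotation, target_genes and background_genes together"
            )
        if (self.ct_table is None) != (self.calibrator is None):
            raise ConfigError("qPCR stage needs ct_table and calibrator together")
        for name in (
            "degradome_reads",
            "transcripts",
            "mature_mirnas",
            "annotation",
            "target_genes",
            "background_genes",
            "ct_table",
        ):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise ConfigError(f"configured input {name!r} not found: {value!r}")


def _setup_logger(out_dir: Path) -> logging.Logger:
    logger = logging.getLogger(f"heteromir.run.{out_dir}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    return logger


def run_heterosis_analysis(config: RunConfig) -> dict[str, Any]:
    """Run the full analysis described by ``config``.

    Writes stage TSVs under ``out_dir/{de,classify,degradome,enrich,qpcr}``,
    a run log, and ``summary.json``; returns the summary dict.  The run is
    deterministic: no stage draws random numbers, so identical inputs give
    identical outputs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger = _setup_logger(out)
    summary: dict[str, Any] = {"inputs": {}, "triads": {}}

    for name in ("counts", "design", "degradome_reads", "transcripts", "mature_mirnas",
                 "annotation", "target_genes", "background_genes", "ct_table"):
        value = getattr(config, name)
        if value is not None:
            summary["inputs"][name] = {"path": str(value), "md5": md5sum(value)}
            logger.info("input %s=%s md5=%s", name, value, summary["inputs"][name]["md5"])

    # --- expression: TPM + per-triad DE ------------------------------------
    try:
        counts = read_counts(config.counts)
        design = TriadDesign.read_tsv(config.design)
    except (ValueError, KeyError) as exc:
        raise DataError(f"stage=load: {exc}") from exc
    (out / "de").mkdir(exist_ok=True)
    (out / "classify").mkdir(exist_ok=True)
    try:
        tpm = tpm_normalize(counts)
    except ValueError as exc:
        raise DataError(f"stage=tpm: {exc}") from exc
    tpm.to_csv(out / "de" / "tpm.tsv", sep="\t", index_label="mirna")
    logger.info("stage=tpm rows=%d samples=%d", *tpm.shape)

    classifications: dict[str, pd.DataFrame] = {}
    scaled_sets: dict[str, set[str]] = {}
    de_frames = []
    for triad in design.triads:
        try:
            hyb = design.samples(triad, "hybrid")
            mat = design.samples(triad, "maternal")
            pat = design.samples(triad, "paternal")
        except KeyError as exc:
            raise DataError(f"stage=de triad={triad}: {exc}") from exc
        de_m = differential_test(
            tpm, hyb, mat, contrast=f"{triad}:hybrid_vs_maternal",
            pseudocount=config.pseudocount, alpha=config.alpha,
            lfc_threshold=config.lfc_threshold, ttest=config.ttest,
        )
        de_p = differential_test(
            tpm, hyb, pat, contrast=f"{triad}:hybrid_vs_paternal",
            pseudocount=config.pseudocount, alpha=config.alpha,
            lfc_threshold=config.lfc_threshold, ttest=config.ttest,
        )
        de_frames += [de_m, de_p]
        union = scaled_union(
            de_m.loc[de_m["significant"], "mirna"],
            de_p.loc[de_p["significant"], "mirna"],
        )
        scaled_sets[triad] = set(union.union)
        logger.info(
            "stage=de triad=%s vs_maternal=%d vs_paternal=%d common=%d union=%d",
            triad, union.n_vs_maternal, union.n_vs_paternal, union.n_common, union.n_union,
        )

        table = classify_triad_table(
            tpm, hyb, mat, pat, triad, mirnas=sorted(union.union), epsilon=config.da_epsilon
        )
        classifications[triad] = table
        tally = tally_direction(
            [None if np.isnan(v) else v for v in table["da"]]
        )
        table_out = table.copy()
        table_out["da"] = table_out["da"].round(2)
        table_out.to_csv(out / "classify" / f"{triad}_da.tsv", sep="\t", index=False)
        logger.info(
            "stage=classify triad=%s scaled=%d induced=%d repressed=%d pct_repressed=%s",
            triad, len(table), tally.n_induced, tally.n_repressed, tally.percent_repressed,
        )
        summary["triads"][triad] = {
            "de_vs_maternal": union.n_vs_maternal,
            "de_vs_paternal": union.n_vs_paternal,
            "de_common": union.n_common,
            "scaled_union": union.n_union,
            "n_induced": tally.n_induced,
            "n_repressed": tally.n_repressed,
            "n_neutral": tally.n_neutral,
            "n_undefined": tally.n_undefined,
            "percent_repressed": tally.percent_repressed,
            "category_counts": table["category"].value_counts().to_dict(),
        }
    pd.concat(de_frames, ignore_index=True).to_csv(out / "de" / "de_results.tsv", sep="\t", index=False)

    # --- cross-triad overlap and family tables -----------------------------
    if len(scaled_sets) >= 2:
        regions = cross_hybrid_overlap(scaled_sets)
        region_df = pd.DataFrame(
            [{"triads": " & ".join(k), "count": v} for k, v in sorted(regions.items())]
        )
        region_df.to_csv(out / "classify" / "venn_regions.tsv", sep="\t", index=False)
        summary["venn"] = {
            "common_all": regions[tuple(sorted(scaled_sets))],
            "unique": {t: regions[(t,)] for t in sorted(scaled_sets)},
        }
        logger.info("stage=venn regions=%d common_all=%d", len(regions), summary["venn"]["common_all"])

    families = sorted(
        {family_of(m) for table in classifications.values() for m in table["mirna"]}
    )
    summary["families"] = {}
    for family in families:
        table = family_pattern_table(classifications, family)
        if table.empty:
            continue
        format_family_table(table).to_csv(
            out / "classify" / f"family_{family}.tsv", sep="\t", index_label="mirna"
        )
        summary["families"][family] = int(len(table))
    logger.info("stage=families n=%d", len(summary["families"]))

    # --- optional degradome stage ------------------------------------------
    if config.degradome_reads:
        (out / "degradome").mkdir(exist_ok=True)
        transcripts = read_fasta(config.transcripts)
        mirnas = read_fasta(config.mature_mirnas)
        if not transcripts:
            raise DataError("stage=degradome: empty transcript FASTA")
        reads = list(read_fasta(config.degradome_reads).items())
        profiles, stats = deg.map_degradome_reads(reads, transcripts)
        sites = deg.call_cleavage_sites(
            profiles, mirnas, transcripts,
            max_score=config.max_duplex_score, min_reads=config.min_site_reads,
        )
        sites.to_csv(out / "degradome" / "cleavage_sites.tsv", sep="\t", index=False)
        for _, site in sites.iterrows():
            tp = deg.tplot_table(profiles[site["transcript"]], int(site["position"]))
            tp.to_csv(
                out / "degradome" / f"tplot_{site['mirna']}_{site['transcript']}_{site['position']}.tsv",
                sep="\t", index=False,
            )
        summary["degradome"] = {
            "n_reads": stats.n_reads,
            "n_mapped": stats.n_mapped,
            "n_sites": int(len(sites)),
            "n_category0": int((sites["category"] == 0).sum()),
        }
        logger.info(
            "stage=degradome reads=%d mapped=%d sites=%d",
            stats.n_reads, stats.n_mapped, len(sites),
        )

    # --- optional enrichment stage ------------------------------------------
    if config.annotation:
        (out / "enrich").mkdir(exist_ok=True)
        ann = read_annotation(config.annotation)
        targets = [l.strip() for l in open(config.target_genes) if l.strip()]
        bg = [l.strip() for l in open(config.background_genes) if l.strip()]
        try:
            enrichment = enr.hypergeometric_enrichment(
                targets, bg, ann, alpha=config.enrichment_alpha
            )
        except ValueError as exc:
            raise DataError(f"stage=enrich: {exc}") from exc
        enrichment.to_csv(out / "enrich" / "enrichment.tsv", sep="\t", index=False)
        summary["enrichment"] = {
            "n_terms": int(len(enrichment)),
            "n_significant": int(enrichment["significant"].sum()),
        }
        logger.info("stage=enrich terms=%d significant=%d",
                    len(enrichment), summary["enrichment"]["n_significant"])

    # --- optional qPCR stage -------------------------------------------------
    if config.ct_table:
        (out / "qpcr").mkdir(exist_ok=True)
        ct = read_ct_table(config.ct_table)
        try:
            rel = enr.delta_delta_ct(ct, config.calibrator)
            letters = enr.lsd_groups(
                {
                    s: (-(g["target_ct"] - g["reference_ct"])).tolist()
                    for s, g in ct.groupby("sample")
                }
            )
        except ValueError as exc:
            raise DataError(f"stage=qpcr: {exc}") from exc
        rel["lsd_letters"] = rel["sample"].map(letters)
        rel.to_csv(out / "qpcr" / "relative_expression.tsv", sep="\t", index=False)
        summary["qpcr"] = {
            "n_samples": int(len(rel)),
            "fold_changes": dict(zip(rel["sample"], rel["fold_change"].round(4))),
        }
        logger.info("stage=qpcr samples=%d", len(rel))

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    logger.info("run complete")
    return summary
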