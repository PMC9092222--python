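"""One-call orchestration of the annotation and comparison pipelines.

``run_annotate`` composes scan -> trim -> classify on a protein catalog;
``run_compare`` composes normalize -> aggregate -> age-match -> test on an
ORF count table. Every run writes the resolved configuration next to its
outputs, and stage-level counts (kept/removed per filter, with reasons)
go into the summary, since the filters are the auditable surface of the
method.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import abundance_stats, align_trim, domain_scan, formats_io, jc_classify
from .records import ProteinRecord

__all__ = [
    "PipelineConfig",
    "run_annotate",
    "run_compare",
    "load_consortium_inventory",
    "consortium_summary",
]


@dataclass
class PipelineConfig:
    """Paths and thresholds; defaults are the published values."""

    proteins: str | None = None
    profile: str | None = None
    panel_labels: str | None = None
    panel_rows: str | None = None
    flags: str | None = None
    counts: str | None = None
    orf_meta: str | None = None
    sample_meta: str | None = None
    out_dir: str = "tirscan_out"
    bit_floor: float = 12.0
    overlap_frac: float = 0.33
    gap_frac: float = 0.15
    max_jc: float = 1.75
    min_residues: int = 98
    catalytic_column: int = 73
    flank: int = 4
    n_boot: int = 10_000
    seed: int = 0

    def write_resolved(self, out_dir: Path) -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "config_resolved.yaml", "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class AnnotateResult:
    hits: list
    classifications: list
    summary: dict = field(default_factory=dict)


def _read_flags(path: str | Path) -> dict[str, bool]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    return {r.protein_id: bool(r.flag) for r in df.itertuples(index=False)}


def run_annotate(config: PipelineConfig) -> AnnotateResult:
    """Scan a catalog, trim the detected domains, classify them, and write
    hits.tsv / trimmed.tsv / classes.tsv / summary.json."""
    out_dir = Path(config.out_dir)
    config.write_resolved(out_dir)
    catalog = (
        formats_io.read_fasta(config.proteins) if config.proteins else []
    )
    profile = formats_io.parse_profile(
        config.profile, catalytic_column=None
    )
    profile.catalytic_column = min(config.catalytic_column, profile.M)
    flags = _read_flags(config.flags) if config.flags else None

    raw = domain_scan.search_profile(catalog, profile)
    included = domain_scan.apply_inclusion(raw, profile, flags)
    deduped = domain_scan.dedup_overlaps(
        included, known_proteins={p.id for p in catalog}
    )
    named = domain_scan.name_domains(deduped)
    formats_io.write_domain_table(named, out_dir / "hits.tsv")

    by_id: dict[str, ProteinRecord] = {p.id: p for p in catalog}
    extracted = {
        h.domain_id: domain_scan.extract_domain(h, by_id[h.protein_id], flank=0)
        for h in named
    }
    rows = align_trim.map_many(extracted, profile)
    report = align_trim.gap_filter(rows, max_gap_fraction=config.gap_frac)
    formats_io.write_trimmed_tsv(
        rows, out_dir / "trimmed.tsv", kept={r.seq_id for r in report.kept}
    )

    panel = None
    classifications = []
    if config.panel_labels and config.panel_rows:
        panel = formats_io.read_panel(config.panel_labels, config.panel_rows)
        classifications = jc_classify.classify_many(
            report.kept,
            panel,
            max_jc=config.max_jc,
            min_residues=config.min_residues,
            catalytic_column=min(config.catalytic_column, profile.M),
        )
        formats_io.write_classifications(
            classifications, out_dir / "classes.tsv"
        )

    sample_of = {p.id: (p.sample_id or "all") for p in catalog}
    per_sample: dict[str, list[str]] = {}
    for h in named:
        per_sample.setdefault(sample_of.get(h.protein_id, "all"), []).append(
            h.domain_id
        )
    label_counts: dict[str, int] = {}
    reason_counts: dict[str, int] = {}
    for c in classifications:
        label_counts[c.label] = label_counts.get(c.label, 0) + 1
        reason_counts[c.reason] = reason_counts.get(c.reason, 0) + 1
    summary = {
        "n_proteins": len(catalog),
        "n_raw_hits": len(raw),
        "n_after_inclusion": len(included),
        "n_after_dedup": len(deduped),
        "n_trimmed_kept": len(report.kept),
        "n_trimmed_removed": len(report.removed),
        "gap_filter_reasons": report.reasons,
        "labels": label_counts,
        "reasons": reason_counts,
        "richness_per_sample": abundance_stats.tir_richness(per_sample),
        "seed": config.seed,
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return AnnotateResult(hits=named, classifications=classifications, summary=summary)


def run_compare(config: PipelineConfig, class_labels: list[str] | None = None) -> dict:
    """Normalized class-abundance comparison between groups; writes
    class_abundance.tsv and comparison.json."""
    out_dir = Path(config.out_dir)
    config.write_resolved(out_dir)
    wide, lengths, labels = formats_io.read_orf_counts(
        config.counts, config.orf_meta
    )
    metas, depth = formats_io.read_sample_meta(config.sample_meta)
    metas = [m for m in metas if m.sample_id in set(wide.index)]
    import numpy as np

    samples = [m.sample_id for m in metas]
    wide = wide.loc[samples]
    total = np.array(
        [depth.get(s, float(wide.loc[s].sum())) for s in samples]
    )
    table = abundance_stats.OrfCountTable(
        samples=samples,
        orf_ids=list(wide.columns),
        orf_lengths_nt=lengths,
        counts=wide.to_numpy(int),
        total_mapped=total,
    )
    norm = abundance_stats.normalize_counts(table)
    class_ab = abundance_stats.aggregate_by_class(norm, labels)
    class_ab.to_csv(out_dir / "class_abundance.tsv", sep="\t")
    if class_labels is None:
        class_labels = [
            c
            for c in class_ab.columns
            if c not in ("unclassified", abundance_stats.ALL_TIR_COLUMN)
        ] + [abundance_stats.ALL_TIR_COLUMN]
    results = {}
    for i, label in enumerate(class_labels):
        comp = abundance_stats.compare_groups(
            class_ab,
            metas,
            label,
            n_boot=config.n_boot,
            rng=int(config.seed) + i,
        )
        results[label] = asdict(comp)
    payload = {"seed": config.seed, "n_boot": config.n_boot, "classes": results}
    with open(out_dir / "comparison.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return payload


# ---------------------------------------------------------------------------
# Packaged defined-community inventory


def load_consortium_inventory() -> pd.DataFrame:
    """TIR inventory of the 26-member gnotobiotic consortium.

    One row per printed inventory line: strain, its TIR domain count
    (blank on continuation lines of strains with several active domains),
    the active domain's ID and its validated NAD-hydrolysis product.
    """
    ref = importlib.resources.files("tirscan.data") / "consortium_tir_inventory.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"strain": str})


def consortium_summary() -> dict:
    """Totals over the packaged consortium inventory."""
    df = load_consortium_inventory()
    active = df[df["active_domain_id"] != "none"]
    return {
        "n_strains": int(df["strain"].nunique()),
        "total_tir_domains": int(df["n_tirs"].dropna().sum()),
        "n_active_domains": int(len(active)),
        "active_products": active["product"].value_counts().to_dict(),
    }
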