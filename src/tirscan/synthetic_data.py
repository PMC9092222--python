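"""Synthetic inputs with recorded ground truth for every pipeline stage.

The generators emulate the statistical structure the analyses assume: a
panel of labelled reference TIR domains and mutated descendants at
controlled substitution fractions, proteomes with domains planted at known
coordinates inside random-background flanks, negative-binomial ORF count
tables with a group effect on one product class, and multinomial
COPRO-Seq read tables with spike-ins and distractors.

All randomness flows from one master seed through named substreams, so
fixtures are byte-identical across reruns of the same seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .records import (
    ACTIVE_LABELS,
    AMINO_ACIDS,
    GAP,
    ProfileHMM,
    ProteinRecord,
    ReferencePanel,
    TrimmedRow,
)

__all__ = [
    "substream",
    "GroundTruth",
    "mutate_row",
    "build_toy_profile",
    "default_panel",
    "default_profile",
    "plant_domains",
    "simulate_counts",
    "simulate_coproseq",
]

#: Match columns of the packaged TIR-like profile and its catalytic column.
PANEL_M = 116
PANEL_CATALYTIC = 73


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Named, stable child stream of one master seed.

    The child is seeded with (master_seed, crc32(name)) so adding a new
    stream never perturbs existing ones.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), zlib.crc32(name.encode())])
    )


@dataclass
class GroundTruth:
    """What the generator actually planted, keyed for later scoring."""

    master_seed: int
    planted_intervals: dict[str, list[tuple[int, int, str, int]]] = field(
        default_factory=dict
    )
    true_labels: dict[str, str] = field(default_factory=dict)
    true_abundances: dict[str, float] = field(default_factory=dict)


def _random_residues(rng: np.random.Generator, n: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=n))


def mutate_row(
    seed_row: TrimmedRow,
    n_subs: int,
    preserve_catalytic: bool = True,
    rng: np.random.Generator | int | None = None,
    catalytic_column: int = PANEL_CATALYTIC,
) -> TrimmedRow:
    """Substitute exactly ``n_subs`` residue columns of a trimmed row.

    Each chosen column receives a uniformly drawn *different* residue;
    gapped columns are never touched and no gaps are introduced. With
    ``preserve_catalytic`` the catalytic column is excluded from mutation.
    """
    rng = np.random.default_rng(rng)
    columns = list(seed_row.columns)
    eligible = [
        i
        for i, c in enumerate(columns)
        if c != GAP and not (preserve_catalytic and i == catalytic_column - 1)
    ]
    if n_subs > len(eligible):
        raise ValueError(
            f"n_subs={n_subs} exceeds the {len(eligible)} mutable columns"
        )
    chosen = rng.choice(len(eligible), size=n_subs, replace=False)
    for idx in chosen:
        i = eligible[idx]
        alternatives = [a for a in AMINO_ACIDS if a != columns[i]]
        columns[i] = alternatives[rng.integers(len(alternatives))]
    return TrimmedRow(seq_id=seed_row.seq_id + "_mut", columns="".join(columns))


def build_toy_profile(
    msa: list[str], pseudocount: float = 1.0, name: str = "TIR_toy"
) -> ProfileHMM:
    """Build a simple profile HMM from an ungapped, equal-length MSA.

    Match emissions are Laplace-smoothed column frequencies; insert
    emissions and the background are the smoothed overall residue
    frequencies; transitions are fixed (MM 0.90 / MI 0.05 / MD 0.05,
    IM = II = 0.50, DM = DD = 0.50); the consensus is the column-wise
    argmax. No noise cutoff is set.
    """
    if not msa:
        raise ValueError("MSA must contain at least one sequence")
    lengths = {len(s) for s in msa}
    if len(lengths) > 1:
        raise ValueError(f"MSA sequences have unequal lengths {sorted(lengths)}")
    M = len(msa[0])
    n = len(msa)
    counts = np.zeros((M, 20))
    for seq in msa:
        for k, c in enumerate(seq.upper()):
            if c in AMINO_ACIDS:
                counts[k, AMINO_ACIDS.index(c)] += 1
    match = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 20 * pseudocount)
    overall = counts.sum(axis=0)
    background = (overall + pseudocount) / (overall.sum() + 20 * pseudocount)
    insert = np.tile(background, (M, 1))
    transitions = np.tile(
        np.array([0.90, 0.05, 0.05, 0.50, 0.50, 0.50, 0.50]), (M, 1)
    )
    consensus = "".join(AMINO_ACIDS[int(np.argmax(counts[k]))] for k in range(M))
    del n
    return ProfileHMM(
        name=name,
        M=M,
        match_emissions=match,
        insert_emissions=insert,
        transitions=transitions,
        background=background,
        consensus=consensus,
        noise_cutoff=None,
        catalytic_column=min(PANEL_CATALYTIC, M),
    )


def default_panel(
    master_seed: int = 0,
    n_per_active_label: int = 2,
    n_inactive: int = 2,
    divergence: float = 0.40,
    M: int = PANEL_M,
) -> tuple[ReferencePanel, str]:
    """A synthetic stand-in for the validated-reference panel.

    Returns the panel plus the ancestral consensus sequence. Each reference
    descends from one consensus at the given divergence, so references of
    different labels are mutually far apart (pairwise mismatch ~0.6 at the
    default) while still alignable to a common profile — mimicking distinct
    validated TIR families. Active references keep the catalytic glutamate;
    inactive ones have it substituted.
    """
    rng = substream(master_seed, "panel")
    consensus = list(_random_residues(rng, M))
    consensus[PANEL_CATALYTIC - 1] = "E"
    consensus = "".join(consensus)
    anchor = TrimmedRow(seq_id="consensus", columns=consensus)
    rows: list[TrimmedRow] = []
    labels: dict[str, str] = {}
    n_subs = int(round(divergence * (M - 1)))
    for label in ACTIVE_LABELS:
        for i in range(n_per_active_label):
            ref = mutate_row(anchor, n_subs, preserve_catalytic=True, rng=rng)
            sid = f"ref_{label}_{i + 1}"
            rows.append(TrimmedRow(seq_id=sid, columns=ref.columns))
            labels[sid] = label
    for i in range(n_inactive):
        ref = mutate_row(anchor, n_subs, preserve_catalytic=True, rng=rng)
        cols = list(ref.columns)
        cols[PANEL_CATALYTIC - 1] = "Q"  # catalytically dead
        sid = f"ref_inactive_{i + 1}"
        rows.append(TrimmedRow(seq_id=sid, columns="".join(cols)))
        labels[sid] = "inactive"
    return ReferencePanel(rows=rows, labels=labels), consensus


def default_profile(
    panel: ReferencePanel, consensus: str, pseudocount: float = 1.0
) -> ProfileHMM:
    """Toy profile built from the consensus plus the panel references."""
    msa = [consensus] + [r.columns for r in panel.rows]
    return build_toy_profile(msa, pseudocount=pseudocount)


def plant_domains(
    n_proteins: int,
    panel: ReferencePanel,
    sub_fraction: float = 0.2,
    flank_length_range: tuple[int, int] = (20, 80),
    rng: np.random.Generator | int | None = None,
    master_seed: int = 0,
    preserve_catalytic: bool = True,
) -> tuple[list[ProteinRecord], GroundTruth]:
    """Proteome of background-flanked, mutated reference domains.

    Each protein is random background + one mutated reference (gaps
    dropped) + random background; the truth records the planted interval,
    the source reference, and the substitution count.
    """
    rng = np.random.default_rng(rng) if rng is not None else substream(
        master_seed, "plant_domains"
    )
    truth = GroundTruth(master_seed=master_seed)
    catalog: list[ProteinRecord] = []
    refs = sorted(panel.rows, key=lambda r: r.seq_id)
    lo, hi = flank_length_range
    for i in range(n_proteins):
        ref = refs[rng.integers(len(refs))]
        n_subs = int(round(sub_fraction * ref.residue_count))
        n_subs = min(n_subs, ref.residue_count - 1)
        mutant = mutate_row(
            ref, n_subs, preserve_catalytic=preserve_catalytic, rng=rng
        )
        segment = mutant.columns.replace(GAP, "")
        n_flank = int(rng.integers(lo, hi + 1))
        c_flank = int(rng.integers(lo, hi + 1))
        seq = (
            _random_residues(rng, n_flank)
            + segment
            + _random_residues(rng, c_flank)
        )
        pid = f"prot_{i + 1:04d}"
        catalog.append(ProteinRecord(id=pid, sequence=seq))
        start = n_flank + 1
        end = n_flank + len(segment)
        truth.planted_intervals[pid] = [(start, end, ref.seq_id, n_subs)]
        truth.true_labels[pid] = panel.labels[ref.seq_id]
    return catalog, truth


def _negative_binomial(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB draw parameterized by mean and dispersion: var = mu + a * mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(
    orf_labels: dict[str, str],
    n_per_group: int = 20,
    effect_fold: float = 4.0,
    target_class: str = "v-cADPR-x",
    nb_dispersion: float = 0.3,
    mean_depth: float = 1.0e6,
    rng: np.random.Generator | int | None = None,
    master_seed: int = 0,
    base_mean_range: tuple[float, float] = (10.0, 300.0),
):
    """Negative-binomial ORF count tables with one class enriched in the
    healthy group.

    Baseline ORF means are drawn log-uniformly over ``base_mean_range``;
    samples in the healthy group have the target class scaled by
    ``effect_fold``. Ages are uniform over 6-36 months in both groups so
    age matching is always feasible.
    """
    from .abundance_stats import OrfCountTable, SampleMeta

    rng = np.random.default_rng(rng) if rng is not None else substream(
        master_seed, "simulate_counts"
    )
    orf_ids = sorted(orf_labels)
    if not orf_ids:
        return (
            OrfCountTable(
                samples=[],
                orf_ids=[],
                orf_lengths_nt=np.empty(0),
                counts=np.empty((0, 0), dtype=int),
                total_mapped=np.empty(0),
            ),
            [],
        )
    n_orfs = len(orf_ids)
    lo, hi = base_mean_range
    base_mu = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_orfs))
    lengths = rng.integers(600, 1801, size=n_orfs).astype(float)
    target = np.array([orf_labels[o] == target_class for o in orf_ids])
    samples, meta, count_rows, totals = [], [], [], []
    for group in ("healthy", "malnourished"):
        for i in range(n_per_group):
            sid = f"{group[0].upper()}{i + 1:03d}"
            mu = base_mu * np.where(
                target & (group == "healthy"), effect_fold, 1.0
            )
            row = _negative_binomial(rng, mu, nb_dispersion)
            depth = max(
                float(row.sum()),
                float(rng.normal(mean_depth, 0.1 * mean_depth)),
            )
            samples.append(sid)
            count_rows.append(row)
            totals.append(depth)
            meta.append(
                SampleMeta(
                    sample_id=sid,
                    donor_id=f"PID_{sid}",
                    age_months=float(rng.uniform(6.0, 36.0)),
                    group=group,
                )
            )
    table = OrfCountTable(
        samples=samples,
        orf_ids=orf_ids,
        orf_lengths_nt=lengths,
        counts=np.vstack(count_rows),
        total_mapped=np.array(totals),
    )
    return table, meta


def write_fixtures(
    out_dir,
    master_seed: int = 0,
    n_proteins: int = 200,
    sub_fraction: float = 0.2,
    n_per_group: int = 20,
    effect_fold: float = 4.0,
) -> dict:
    """Write one complete, reproducible fixture set for the pipeline.

    Emits the panel (labels + trimmed rows), the toy profile, a planted
    proteome FASTA, ORF count / metadata / sample tables, COPRO-Seq input
    TSVs, and truth.json. Identical master seeds yield byte-identical
    files.
    """
    import json
    from pathlib import Path

    from . import formats_io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel, consensus = default_panel(master_seed)
    profile = default_profile(panel, consensus)
    formats_io.write_profile(profile, out / "profile.hmm")
    formats_io.write_trimmed_tsv(panel.rows, out / "panel_rows.tsv")
    import pandas as pd

    pd.DataFrame(
        sorted(panel.labels.items()), columns=["seq_id", "label"]
    ).to_csv(out / "panel_labels.tsv", sep="\t", index=False)

    catalog, truth = plant_domains(
        n_proteins, panel, sub_fraction=sub_fraction, master_seed=master_seed
    )
    formats_io.write_fasta(catalog, out / "proteome.fasta")

    orf_labels = dict(truth.true_labels)
    table, metas = simulate_counts(
        orf_labels,
        n_per_group=n_per_group,
        effect_fold=effect_fold,
        master_seed=master_seed,
    )
    formats_io.write_orf_counts(
        table, orf_labels, out / "orf_counts.tsv", out / "orf_meta.tsv"
    )
    depth = dict(zip(table.samples, table.total_mapped))
    formats_io.write_sample_meta(metas, out / "sample_meta.tsv", depth=depth)

    abundances = {
        f"member_{i + 1:02d}": a
        for i, a in enumerate(np.logspace(7, 10, 10))
    }
    sample, cop_truth = simulate_coproseq(abundances, master_seed=master_seed)
    genomes_rows = []
    for g, size in sorted(sample.informative_size.items()):
        role = (
            "spike"
            if g in sample.spike_ins
            else ("distractor" if g in sample.distractors else "member")
        )
        genomes_rows.append((g, size, role))
    pd.DataFrame(
        sorted(sample.reads_per_genome.items()),
        columns=["genome_id", "reads"],
    ).assign(sample_id=sample.sample_id)[["sample_id", "genome_id", "reads"]].to_csv(
        out / "coproseq_reads.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        genomes_rows, columns=["genome_id", "informative_size", "role"]
    ).to_csv(out / "coproseq_genomes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (sample.sample_id, g, a)
            for g, a in sorted(sample.spike_ins.items())
        ],
        columns=["sample_id", "genome_id", "added_equivalents"],
    ).to_csv(out / "coproseq_spikes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(sample.sample_id, sample.mass_g)], columns=["sample_id", "mass_g"]
    ).to_csv(out / "coproseq_masses.tsv", sep="\t", index=False)

    truth_payload = {
        "master_seed": master_seed,
        "planted_intervals": truth.planted_intervals,
        "true_labels": truth.true_labels,
        "coproseq_true_abundances": cop_truth.true_abundances,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_payload, fh, indent=2, sort_keys=True)
    return truth_payload


def simulate_coproseq(
    true_abundances: dict[str, float],
    spikes: dict[str, float] | None = None,
    distractor_noise_level: float = 3.0e5,
    total_reads: int = 1_000_000,
    rng: np.random.Generator | int | None = None,
    master_seed: int = 0,
    n_distractors: int = 5,
    sample_id: str = "cecal_1",
):
    """One multinomial COPRO-Seq sample with spike-ins and distractors.

    Read probabilities are proportional to (genome equivalents present in
    the specimen) x (informative genome size); community genome
    equivalents are abundance x mass, spike-ins contribute their added
    equivalents directly, and distractors sit at ``distractor_noise_level``
    per gram (cross-mapping noise). Returns the sample and its ground
    truth.
    """
    from .records import CoproseqSample

    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    rng = np.random.default_rng(rng) if rng is not None else substream(
        master_seed, "simulate_coproseq"
    )
    if spikes is None:
        spikes = {"spike_A": 1.0e9, "spike_B": 1.0e9}
    members = sorted(true_abundances)
    distractors = {f"distractor_{i + 1}" for i in range(n_distractors)}
    genomes = members + sorted(spikes) + sorted(distractors)
    sizes = {
        g: float(rng.uniform(2.0e6, 6.0e6)) for g in genomes
    }  # informative (uniquely mappable) bases
    mass_g = float(rng.uniform(0.05, 0.2))
    equivalents = {}
    for g in members:
        equivalents[g] = true_abundances[g] * mass_g
    for g in spikes:
        equivalents[g] = spikes[g]
    for g in distractors:
        equivalents[g] = distractor_noise_level * mass_g
    weights = np.array([equivalents[g] * sizes[g] for g in genomes])
    if weights.sum() == 0:
        raise ValueError("all genome weights are zero")
    reads = rng.multinomial(total_reads, weights / weights.sum())
    sample = CoproseqSample(
        sample_id=sample_id,
        reads_per_genome={g: int(r) for g, r in zip(genomes, reads)},
        informative_size=sizes,
        spike_ins=dict(spikes),
        distractors=distractors,
        mass_g=mass_g,
    )
    truth = GroundTruth(
        master_seed=master_seed, true_abundances=dict(true_abundances)
    )
    truth.true_abundances.update({d: distractor_noise_level for d in distractors})
    return sample, truth
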