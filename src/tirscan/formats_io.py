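"""Readers and writers for the external formats the pipeline touches.

Covered formats: protein FASTA, HMMER3 ASCII profiles, per-domain hit
tables (domtblout dialect, written here as TSV), Stockholm / aligned-FASTA
alignments under the A2M case convention, and the tabular TSV inputs of the
abundance and COPRO-Seq stages.

Every reader/writer pair round-trips field-identically for valid inputs.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import AMINO_ACIDS, DomainHit, ProfileHMM, ProteinRecord, TrimmedRow

__all__ = [
    "read_fasta",
    "write_fasta",
    "parse_profile",
    "write_profile",
    "parse_domain_table",
    "write_domain_table",
    "read_alignment_rows",
    "read_trimmed_tsv",
    "write_trimmed_tsv",
    "read_panel",
    "write_classifications",
]

DOMTBL_COLUMNS = [
    "protein_id",
    "model_name",
    "full_seq_bits",
    "domain_bits",
    "hmm_start",
    "hmm_end",
    "ali_start",
    "ali_end",
    "env_start",
    "env_end",
    "accuracy",
    "domain_id",
]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, sample_id: str | None = None) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    Sequences are upper-cased and terminal ``*`` stop characters stripped.
    Duplicate IDs raise ``ValueError`` naming the offending ID.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate FASTA id {entry.id!r} in {path}")
        seen.add(entry.id)
        seq = str(entry.seq).upper().rstrip("*")
        if not seq:
            raise ValueError(f"empty sequence for FASTA id {entry.id!r} in {path}")
        records.append(ProteinRecord(id=entry.id, sequence=seq, sample_id=sample_id))
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path, width: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# HMMER3 ASCII profile dialect
#
# Probabilities are stored as negative natural logs; '*' marks probability
# zero. Node 0 (the begin node) is written with background insert emissions
# and a fixed entry transition line, and ignored on parsing: the aligner
# uses free glocal entry/exit, so the begin node carries no information.

_ENTRY_LINE = "0.00000000  *  *  0.00000000  *  0.00000000  *"


def _fmt(p: float) -> str:
    if p <= 0.0:
        return "*"
    return f"{-math.log(p):.12f}"


def _unfmt(tok: str) -> float:
    if tok == "*":
        return 0.0
    return math.exp(-float(tok))


def write_profile(profile: ProfileHMM, path: str | Path) -> None:
    """Write a profile in the HMMER3 ASCII dialect."""
    lines = [
        "HMMER3/f [tirscan profile]",
        f"NAME  {profile.name}",
        f"LENG  {profile.M}",
        "ALPH  amino",
        "CONS  yes",
    ]
    if profile.noise_cutoff is not None:
        lines.append(f"NC    {profile.noise_cutoff:.2f} {profile.noise_cutoff:.2f};")
    # nominal extreme-value calibration constants so external HMMER tools
    # can attach E-values; the in-package aligner works on bit scores only
    lines.append("STATS LOCAL MSV       -9.0000  0.71000")
    lines.append("STATS LOCAL VITERBI   -9.7000  0.71000")
    lines.append("STATS LOCAL FORWARD   -3.7000  0.71000")
    lines.append("HMM          " + "        ".join(AMINO_ACIDS))
    lines.append(
        "            m->m     m->i     m->d     i->m     i->i     d->m     d->d"
    )
    lines.append("  COMPO   " + "  ".join(_fmt(p) for p in profile.background))
    # Begin node: background inserts, free entry into M1/D1.
    lines.append("          " + "  ".join(_fmt(p) for p in profile.background))
    lines.append("          " + _ENTRY_LINE)
    for k in range(profile.M):
        match = "  ".join(_fmt(p) for p in profile.match_emissions[k])
        lines.append(f"{k + 1:7d}   {match}  {k + 1} {profile.consensus[k]} - - -")
        lines.append(
            "          " + "  ".join(_fmt(p) for p in profile.insert_emissions[k])
        )
        lines.append(
            "          " + "  ".join(_fmt(p) for p in profile.transitions[k])
        )
    lines.append("//")
    Path(path).write_text("\n".join(lines) + "\n")


def parse_profile(
    path: str | Path, catalytic_column: int | None = None
) -> ProfileHMM:
    """Parse an HMMER3 ASCII profile.

    ``catalytic_column`` defaults to column 73 (the catalytic glutamate of
    the clan-level TIR profile) clipped to the model length, for profiles
    shorter than 73 columns.
    """
    text = Path(path).read_text().splitlines()
    name = "unknown"
    M: int | None = None
    noise_cutoff: float | None = None
    i = 0
    if not text or not text[0].startswith("HMMER3"):
        raise ValueError(f"{path}: not an HMMER3 ASCII profile")
    while i < len(text) and not text[i].startswith("HMM "):
        tok = text[i].split()
        if tok:
            if tok[0] == "NAME":
                name = tok[1]
            elif tok[0] == "LENG":
                M = int(tok[1])
            elif tok[0] == "ALPH" and tok[1].lower() != "amino":
                raise ValueError(f"{path}: alphabet {tok[1]!r} is not amino")
            elif tok[0] == "NC":
                noise_cutoff = float(tok[1].rstrip(";"))
        i += 1
    if i == len(text):
        raise ValueError(f"{path}: missing HMM block")
    if M is None:
        raise ValueError(f"{path}: missing LENG line")
    i += 2  # skip HMM header line and transition header line
    background = np.full(20, 1.0 / 20)
    tok = text[i].split()
    if tok and tok[0] == "COMPO":
        background = np.array([_unfmt(t) for t in tok[1:21]])
        i += 1
    i += 2  # begin-node insert emission and transition lines
    match_emissions = np.empty((M, 20))
    insert_emissions = np.empty((M, 20))
    transitions = np.empty((M, 7))
    consensus: list[str] = []
    for k in range(M):
        tok = text[i].split()
        if int(tok[0]) != k + 1:
            raise ValueError(f"{path}: expected node {k + 1}, found {tok[0]!r}")
        match_emissions[k] = [_unfmt(t) for t in tok[1:21]]
        consensus.append(tok[22] if len(tok) > 22 else AMINO_ACIDS[int(np.argmax(match_emissions[k]))])
        insert_emissions[k] = [_unfmt(t) for t in text[i + 1].split()[:20]]
        transitions[k] = [_unfmt(t) for t in text[i + 2].split()[:7]]
        i += 3
    for label, rows in (("match", match_emissions), ("insert", insert_emissions)):
        sums = rows.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-3):
            k = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"{path}: {label} emission row {k + 1} sums to {sums[k]:.6f}"
            )
    if catalytic_column is None:
        catalytic_column = min(73, M)
    return ProfileHMM(
        name=name,
        M=M,
        match_emissions=match_emissions,
        insert_emissions=insert_emissions,
        transitions=transitions,
        background=background,
        consensus="".join(consensus),
        noise_cutoff=noise_cutoff,
        catalytic_column=catalytic_column,
    )


# ---------------------------------------------------------------------------
# Per-domain hit tables (domtblout dialect)


def parse_domain_table(path: str | Path) -> list[DomainHit]:
    """Parse a whitespace-delimited per-domain table.

    Columns follow the domtblout dialect written by :func:`write_domain_table`;
    ``#`` comment lines are skipped. Coordinates stay 1-based inclusive.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            tok = line.split()
            if len(tok) < 11:
                raise ValueError(f"{path}:{lineno}: expected ≥11 fields, got {len(tok)}")
            try:
                hit = DomainHit(
                    protein_id=tok[0],
                    model_name=tok[1],
                    full_seq_bits=float(tok[2]),
                    domain_bits=float(tok[3]),
                    hmm_start=int(tok[4]),
                    hmm_end=int(tok[5]),
                    ali_start=int(tok[6]),
                    ali_end=int(tok[7]),
                    env_start=int(tok[8]),
                    env_end=int(tok[9]),
                    accuracy=float(tok[10]),
                    domain_id=tok[11] if len(tok) > 11 and tok[11] != "-" else "",
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_domain_table(hits: list[DomainHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(DOMTBL_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.protein_id,
                        h.model_name,
                        f"{h.full_seq_bits:.4f}",
                        f"{h.domain_bits:.4f}",
                        str(h.hmm_start),
                        str(h.hmm_end),
                        str(h.ali_start),
                        str(h.ali_end),
                        str(h.env_start),
                        str(h.env_end),
                        f"{h.accuracy:.6f}",
                        h.domain_id or "-",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Imported alignments (Stockholm / aligned FASTA, A2M case convention)


def read_alignment_rows(path: str | Path, fmt: str = "stockholm") -> list[TrimmedRow]:
    """Project an imported alignment onto match columns.

    Under the A2M convention, upper-case residues and ``-`` occupy match
    columns while lower-case residues and ``.`` are insert states; inserts
    are dropped. All projected rows must share one length M.
    """
    alignment = AlignIO.read(str(path), fmt)
    texts = [str(rec.seq) for rec in alignment]
    n_cols = alignment.get_alignment_length()
    # column-wise assignment: any lower-case residue (or '.', where the
    # parser preserves it) marks the whole column as insert-state
    is_insert = [
        any(t[k].islower() or t[k] == "." for t in texts) for k in range(n_cols)
    ]
    rows = []
    for rec, text in zip(alignment, texts):
        kept = [
            ("-" if text[k] in ".-" else text[k].upper())
            for k in range(n_cols)
            if not is_insert[k]
        ]
        rows.append(TrimmedRow(seq_id=rec.id, columns="".join(kept)))
    return rows


# ---------------------------------------------------------------------------
# Trimmed-row and panel TSVs


def write_trimmed_tsv(
    rows: list[TrimmedRow], path: str | Path, kept: set[str] | None = None
) -> None:
    df = pd.DataFrame(
        {
            "seq_id": [r.seq_id for r in rows],
            "columns": [r.columns for r in rows],
            "gap_count": [r.gap_count for r in rows],
            "kept": [True if kept is None else (r.seq_id in kept) for r in rows],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_trimmed_tsv(path: str | Path) -> list[TrimmedRow]:
    df = pd.read_csv(path, sep="\t", dtype={"seq_id": str, "columns": str})
    return [
        TrimmedRow(seq_id=row.seq_id, columns=row.columns)
        for row in df.itertuples(index=False)
    ]


def read_panel(labels_tsv: str | Path, rows_tsv: str | Path):
    """Load a reference panel from a label TSV plus a trimmed-row TSV."""
    from .records import ReferencePanel

    labels_df = pd.read_csv(labels_tsv, sep="\t", dtype=str)
    if not {"seq_id", "label"} <= set(labels_df.columns):
        raise ValueError(f"{labels_tsv}: panel TSV needs seq_id and label columns")
    labels = dict(zip(labels_df["seq_id"], labels_df["label"]))
    rows = read_trimmed_tsv(rows_tsv)
    return ReferencePanel(rows=rows, labels=labels)


# ---------------------------------------------------------------------------
# Tabular inputs of the abundance and COPRO-Seq stages


def read_orf_counts(counts_tsv: str | Path, orf_meta_tsv: str | Path):
    """Load an ORF count table plus the ORF product labels.

    ``counts_tsv`` columns: sample_id, orf_id, count. ``orf_meta_tsv``
    columns: orf_id, length_nt, label. Returns (OrfCountTable-without-depth
    arrays, labels dict); per-sample depth comes from the sample metadata.
    """
    counts = pd.read_csv(counts_tsv, sep="\t", dtype={"sample_id": str, "orf_id": str})
    meta = pd.read_csv(orf_meta_tsv, sep="\t", dtype={"orf_id": str, "label": str})
    wide = counts.pivot_table(
        index="sample_id", columns="orf_id", values="count", fill_value=0
    )
    meta = meta.set_index("orf_id").loc[list(wide.columns)]
    labels = meta["label"].to_dict()
    return wide, meta["length_nt"].to_numpy(float), labels


def write_orf_counts(table, labels: dict[str, str], counts_tsv, orf_meta_tsv) -> None:
    rows = []
    for i, sid in enumerate(table.samples):
        for j, orf in enumerate(table.orf_ids):
            rows.append((sid, orf, int(table.counts[i, j])))
    pd.DataFrame(rows, columns=["sample_id", "orf_id", "count"]).to_csv(
        counts_tsv, sep="\t", index=False
    )
    pd.DataFrame(
        {
            "orf_id": table.orf_ids,
            "length_nt": table.orf_lengths_nt.astype(int),
            "label": [labels.get(o, "unclassified") for o in table.orf_ids],
        }
    ).to_csv(orf_meta_tsv, sep="\t", index=False)


def read_sample_meta(path: str | Path):
    """Sample metadata TSV: sample_id, donor_id, age_months, group
    [, total_mapped]."""
    from .abundance_stats import SampleMeta

    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "donor_id": str})
    metas = [
        SampleMeta(
            sample_id=r.sample_id,
            donor_id=r.donor_id,
            age_months=float(r.age_months),
            group=r.group,
        )
        for r in df.itertuples(index=False)
    ]
    depth = (
        dict(zip(df["sample_id"], df["total_mapped"].astype(float)))
        if "total_mapped" in df.columns
        else {}
    )
    return metas, depth


def write_sample_meta(metas, path: str | Path, depth: dict[str, float] | None = None) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metas],
            "donor_id": [m.donor_id for m in metas],
            "age_months": [m.age_months for m in metas],
            "group": [m.group for m in metas],
        }
    )
    if depth:
        df["total_mapped"] = [depth[m.sample_id] for m in metas]
    df.to_csv(path, sep="\t", index=False)


def read_coproseq_tables(
    reads_tsv: str | Path,
    genomes_tsv: str | Path,
    spikes_tsv: str | Path,
    masses_tsv: str | Path,
):
    """Assemble :class:`CoproseqSample` objects from the four input TSVs.

    reads: sample_id, genome_id, reads; genomes: genome_id,
    informative_size, role (member|spike|distractor); spikes: sample_id,
    genome_id, added_equivalents; masses: sample_id, mass_g.
    """
    from .records import CoproseqSample

    reads = pd.read_csv(reads_tsv, sep="\t", dtype={"sample_id": str, "genome_id": str})
    genomes = pd.read_csv(genomes_tsv, sep="\t", dtype={"genome_id": str, "role": str})
    spikes = pd.read_csv(spikes_tsv, sep="\t", dtype={"sample_id": str, "genome_id": str})
    masses = pd.read_csv(masses_tsv, sep="\t", dtype={"sample_id": str})
    sizes = dict(zip(genomes["genome_id"], genomes["informative_size"].astype(float)))
    distractors = set(genomes.loc[genomes["role"] == "distractor", "genome_id"])
    samples = []
    for sid, grp in reads.groupby("sample_id"):
        spike_rows = spikes[spikes["sample_id"] == sid]
        mass_rows = masses[masses["sample_id"] == sid]
        if mass_rows.empty:
            raise ValueError(f"no mass recorded for sample {sid!r}")
        samples.append(
            CoproseqSample(
                sample_id=str(sid),
                reads_per_genome=dict(
                    zip(grp["genome_id"], grp["reads"].astype(int))
                ),
                informative_size=sizes,
                spike_ins=dict(
                    zip(
                        spike_rows["genome_id"],
                        spike_rows["added_equivalents"].astype(float),
                    )
                ),
                distractors=distractors,
                mass_g=float(mass_rows["mass_g"].iloc[0]),
            )
        )
    return samples


def write_classifications(results, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "query_id": [r.query_id for r in results],
            "nearest_ref_id": [r.nearest_ref_id or "-" for r in results],
            "min_jc": [r.min_jc for r in results],
            "aligned_residues": [r.aligned_residues for r in results],
            "catalytic_ok": [r.catalytic_ok for r in results],
            "label": [r.label for r in results],
            "reason": [r.reason for r in results],
        }
    )
    df.to_csv(path, sep="\t", index=False)
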