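"""Core data containers shared across the pipeline stages.

All residue coordinates are 1-based inclusive throughout the package,
matching the HMMER domtblout convention. The amino-acid alphabet is the
20 canonical residues in HMMER column order, plus ``X`` for ambiguity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Canonical residue order (HMMER emission-column order).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP = "-"


@dataclass
class ProteinRecord:
    """One protein from a catalog, keyed by its locus tag."""

    id: str
    sequence: str
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record with empty id")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS + "X")
        if bad:
            raise ValueError(
                f"protein {self.id!r} contains non-amino-acid characters: "
                f"{sorted(bad)}"
            )


@dataclass
class ProfileHMM:
    """A profile hidden Markov model over amino acids.

    ``match_emissions`` and ``insert_emissions`` are (M, 20) probability
    arrays; ``transitions`` is an (M, 7) array in HMMER order
    (MM, MI, MD, IM, II, DM, DD), where row k holds the transitions out of
    model position k+1. ``catalytic_column`` is the 1-based match column
    holding the catalytic glutamate (73 in the 116-column clan-level TIR
    profile).
    """

    name: str
    M: int
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: np.ndarray
    background: np.ndarray
    consensus: str
    noise_cutoff: float | None = None
    catalytic_column: int = 73

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        self.validate()

    def validate(self, tol: float = 1e-6) -> None:
        if self.match_emissions.shape != (self.M, 20):
            raise ValueError("match_emissions must be (M, 20)")
        if self.insert_emissions.shape != (self.M, 20):
            raise ValueError("insert_emissions must be (M, 20)")
        if self.transitions.shape != (self.M, 7):
            raise ValueError("transitions must be (M, 7)")
        if self.background.shape != (20,):
            raise ValueError("background must have 20 entries")
        for label, rows in (
            ("match emission", self.match_emissions),
            ("insert emission", self.insert_emissions),
            ("background", self.background[None, :]),
        ):
            sums = rows.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=tol):
                k = int(np.argmax(np.abs(sums - 1.0)))
                raise ValueError(
                    f"{label} row {k + 1} sums to {sums[k]:.8f}, not 1"
                )
        # Transition groups: M->{M,I,D}, I->{M,I}, D->{M,D}.
        groups = (
            ("M", self.transitions[:, 0:3].sum(axis=1)),
            ("I", self.transitions[:, 3:5].sum(axis=1)),
            ("D", self.transitions[:, 5:7].sum(axis=1)),
        )
        for label, sums in groups:
            if not np.allclose(sums, 1.0, atol=tol):
                k = int(np.argmax(np.abs(sums - 1.0)))
                raise ValueError(
                    f"{label}-state transition group at position {k + 1} "
                    f"sums to {sums[k]:.8f}, not 1"
                )
        if len(self.consensus) != self.M:
            raise ValueError("consensus length must equal M")
        if not (1 <= self.catalytic_column <= self.M):
            raise ValueError("catalytic_column outside [1, M]")


@dataclass(eq=False)  # identity semantics: hits are mutated across stages
class DomainHit:
    """One detected TIR domain on one protein."""

    protein_id: str
    model_name: str
    full_seq_bits: float
    domain_bits: float
    hmm_start: int
    hmm_end: int
    ali_start: int
    ali_end: int
    env_start: int
    env_end: int
    accuracy: float
    domain_id: str = ""

    def __post_init__(self) -> None:
        if not (self.env_start <= self.ali_start <= self.ali_end <= self.env_end):
            raise ValueError(
                f"hit on {self.protein_id}: envelope must contain the "
                f"alignment interval (env {self.env_start}..{self.env_end}, "
                f"ali {self.ali_start}..{self.ali_end})"
            )
        if not (1 <= self.hmm_start <= self.hmm_end):
            raise ValueError("hmm interval must be 1-based and non-empty")
        if not (0.0 <= self.accuracy <= 1.0):
            raise ValueError("accuracy must lie in [0, 1]")

    @property
    def ali_length(self) -> int:
        return self.ali_end - self.ali_start + 1

    @property
    def env_length(self) -> int:
        return self.env_end - self.env_start + 1


@dataclass
class TrimmedRow:
    """A sequence projected onto the profile's M match columns.

    ``columns`` is a length-M string of residues and ``-`` gaps; insert-state
    residues have been removed.
    """

    seq_id: str
    columns: str

    def __post_init__(self) -> None:
        bad = set(self.columns) - set(AMINO_ACIDS + "X" + GAP)
        if bad:
            raise ValueError(f"trimmed row {self.seq_id!r}: bad symbols {sorted(bad)}")

    @property
    def M(self) -> int:
        return len(self.columns)

    @property
    def gap_count(self) -> int:
        return self.columns.count(GAP)

    @property
    def residue_count(self) -> int:
        return self.M - self.gap_count


#: Product labels a validated reference may carry.
ACTIVE_LABELS = ("ADPR", "cADPR", "v-cADPR-x", "v-cADPR-y")
ALL_LABELS = ACTIVE_LABELS + ("inactive",)


@dataclass
class ReferencePanel:
    """Biochemically validated TIR domains with their NADase product labels."""

    rows: list[TrimmedRow]
    labels: dict[str, str]

    def __post_init__(self) -> None:
        for row in self.rows:
            if row.seq_id not in self.labels:
                raise ValueError(f"panel row {row.seq_id!r} has no label")
            if self.labels[row.seq_id] not in ALL_LABELS:
                raise ValueError(
                    f"panel row {row.seq_id!r}: unknown label "
                    f"{self.labels[row.seq_id]!r}"
                )
        if not any(self.labels[r.seq_id] in ACTIVE_LABELS for r in self.rows):
            raise ValueError("panel must contain at least one active reference")


@dataclass
class ClassificationResult:
    """Nearest-validated-reference classification of one query TIR."""

    query_id: str
    nearest_ref_id: str | None
    min_jc: float
    compared_positions: int
    aligned_residues: int
    catalytic_ok: bool
    label: str
    reason: str  # ok | distance_exceeded | too_few_residues | no_catalytic_glu | no_finite_distance

    def __post_init__(self) -> None:
        if self.label != "unclassified" and not (
            math.isfinite(self.min_jc) and self.catalytic_ok
        ):
            raise ValueError("classified result must pass all gates")


@dataclass
class CoproseqSample:
    """One COPRO-Seq sample: mapped reads, spike-ins, distractors, mass."""

    sample_id: str
    reads_per_genome: dict[str, int]
    informative_size: dict[str, float]
    spike_ins: dict[str, float]  # genome -> genome equivalents added
    distractors: set[str] = field(default_factory=set)
    mass_g: float = 0.1

    def __post_init__(self) -> None:
        if self.mass_g <= 0:
            raise ValueError("sample mass must be positive")
        community = set(self.reads_per_genome) - set(self.spike_ins) - self.distractors
        if set(self.spike_ins) & self.distractors:
            raise ValueError("spike-in genomes cannot also be distractors")
        for g in self.reads_per_genome:
            if g not in self.informative_size:
                raise ValueError(f"genome {g!r} has reads but no informative size")
        del community  # disjointness of roles enforced above
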