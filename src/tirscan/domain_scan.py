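"""TIR-domain detection: profile search, inclusion filter, overlap
deduplication, naming, and sequence extraction.

Inclusion follows the published two-arm rule: a protein's hits are kept if
its full-sequence bit score exceeds the profile's noise cutoff, or if the
protein carries an imported domain-signature flag (from an external
annotation run) and the domain's own bit score exceeds 12. Overlapping
annotations on one protein are resolved at the 33% envelope-overlap
threshold with precedence bit score > alignment length > alignment
accuracy.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from ._viterbi import ProfileScorer, viterbi_glocal
from .records import DomainHit, ProfileHMM, ProteinRecord

__all__ = [
    "search_profile",
    "apply_inclusion",
    "dedup_overlaps",
    "name_domains",
    "extract_domain",
    "BIT_SCORE_FLOOR",
    "OVERLAP_FRACTION",
]

#: Fallback per-domain bit-score floor (strict inequality).
BIT_SCORE_FLOOR = 12.0
#: Minimum envelope overlap fraction at which two hits are deemed redundant.
OVERLAP_FRACTION = 0.33
#: Flat envelope extension beyond the alignment interval, in residues.
ENV_EXTENSION = 2
#: Maximum hits extracted per protein by iterative masking.
MAX_HITS_PER_PROTEIN = 8


def search_profile(
    catalog: list[ProteinRecord], profile: ProfileHMM
) -> list[DomainHit]:
    """Detect domains in every catalog protein by glocal Viterbi alignment.

    Multiple hits per protein are extracted iteratively: after each best
    path, its aligned residues are hard-masked and the search repeats (at
    most :data:`MAX_HITS_PER_PROTEIN` rounds). Hits with non-positive
    domain bit score are discarded. The envelope is the alignment interval
    extended by :data:`ENV_EXTENSION` residues on each side, bounded by the
    protein ends and by previously extracted hits.
    """
    scorer = ProfileScorer(profile)
    hits: list[DomainHit] = []
    for protein in catalog:
        encoded = scorer.encode(protein.sequence)
        L = len(encoded)
        mask = np.zeros(L, dtype=bool)
        protein_hits: list[DomainHit] = []
        for _ in range(MAX_HITS_PER_PROTEIN):
            aln = viterbi_glocal(scorer, encoded, mask if mask.any() else None)
            if aln is None or aln.score_bits <= 0.0:
                break
            env_start = aln.ali_start
            for _step in range(ENV_EXTENSION):
                if env_start > 1 and not mask[env_start - 2]:
                    env_start -= 1
            env_end = aln.ali_end
            for _step in range(ENV_EXTENSION):
                if env_end < L and not mask[env_end]:
                    env_end += 1
            protein_hits.append(
                DomainHit(
                    protein_id=protein.id,
                    model_name=profile.name,
                    full_seq_bits=0.0,  # assigned once all hits are known
                    domain_bits=aln.score_bits,
                    hmm_start=aln.hmm_start,
                    hmm_end=aln.hmm_end,
                    ali_start=aln.ali_start,
                    ali_end=aln.ali_end,
                    env_start=env_start,
                    env_end=env_end,
                    accuracy=aln.n_match_columns / profile.M,
                )
            )
            mask[aln.ali_start - 1 : aln.ali_end] = True
        total = sum(h.domain_bits for h in protein_hits)
        for h in protein_hits:
            h.full_seq_bits = total
        hits.extend(sorted(protein_hits, key=lambda h: h.env_start))
    return hits


def apply_inclusion(
    hits: list[DomainHit],
    profile: ProfileHMM | None = None,
    imported_flags: dict[str, bool] | None = None,
) -> list[DomainHit]:
    """Apply the two-arm inclusion criterion.

    A hit is kept iff its full-sequence bit score exceeds the profile's
    noise cutoff (arm i), or its protein carries an imported signature flag
    and the domain bit score strictly exceeds 12 (arm ii). With neither a
    noise cutoff nor flags available, the fallback is the strict
    domain-bit floor alone.
    """
    cutoff = profile.noise_cutoff if profile is not None else None
    kept = []
    for h in hits:
        arm_i = cutoff is not None and h.full_seq_bits > cutoff
        if imported_flags is not None:
            arm_ii = bool(imported_flags.get(h.protein_id, False)) and (
                h.domain_bits > BIT_SCORE_FLOOR
            )
        elif cutoff is None:
            arm_ii = h.domain_bits > BIT_SCORE_FLOOR
        else:
            arm_ii = False
        if arm_i or arm_ii:
            kept.append(h)
    return kept


def _overlap_fraction(a: DomainHit, b: DomainHit) -> float:
    shared = min(a.env_end, b.env_end) - max(a.env_start, b.env_start) + 1
    if shared <= 0:
        return 0.0
    return shared / min(a.env_length, b.env_length)


def precedence_key(h: DomainHit):
    """Sort key implementing bits > alignment length > accuracy precedence,
    with (model_name, env_start) ascending as the final deterministic
    tie-break."""
    return (-h.domain_bits, -h.ali_length, -h.accuracy, h.model_name, h.env_start)


def dedup_overlaps(
    hits: list[DomainHit], known_proteins: set[str] | None = None
) -> list[DomainHit]:
    """Resolve redundant annotations per protein.

    Hits are visited in precedence order and accepted greedily; a candidate
    is rejected if its envelope overlaps any already-accepted hit on the
    same protein by at least 33% of the shorter envelope. Output is ordered
    by (protein_id, env_start).
    """
    if known_proteins is not None:
        unknown = {h.protein_id for h in hits} - known_proteins
        if unknown:
            raise ValueError(f"hits on unknown proteins: {sorted(unknown)}")
    by_protein: dict[str, list[DomainHit]] = defaultdict(list)
    for h in hits:
        by_protein[h.protein_id].append(h)
    out: list[DomainHit] = []
    for pid in sorted(by_protein):
        accepted: list[DomainHit] = []
        for h in sorted(by_protein[pid], key=precedence_key):
            if all(_overlap_fraction(h, a) < OVERLAP_FRACTION for a in accepted):
                accepted.append(h)
        out.extend(sorted(accepted, key=lambda h: h.env_start))
    return out


def name_domains(hits: list[DomainHit]) -> list[DomainHit]:
    """Assign ``<protein_id>.<model_name>.<k>`` domain IDs.

    ``k`` counts hits of the same model within the protein in envelope
    order, starting at 1.
    """
    counters: dict[tuple[str, str], int] = defaultdict(int)
    ordered = sorted(hits, key=lambda h: (h.protein_id, h.env_start))
    for h in ordered:
        key = (h.protein_id, h.model_name)
        counters[key] += 1
        h.domain_id = f"{h.protein_id}.{h.model_name}.{counters[key]}"
    return sorted(hits, key=lambda h: (h.protein_id, h.env_start))


def extract_domain(hit: DomainHit, protein: ProteinRecord, flank: int = 4) -> str:
    """Extract the domain sequence for classification or construct design.

    The substring runs from ``flank`` residues before the first aligning
    position (or the protein start, when fewer than ``flank`` residues
    precede it) through the envelope end. Construct design uses the default
    4-residue flank; classification extracts from the same rule.
    """
    if hit.protein_id != protein.id:
        raise ValueError(f"hit {hit.domain_id or hit.protein_id} does not belong to {protein.id}")
    if hit.env_end > len(protein.sequence) or hit.ali_start < 1:
        raise ValueError(
            f"hit coordinates {hit.ali_start}..{hit.env_end} out of range for "
            f"{protein.id} (length {len(protein.sequence)})"
        )
    start = max(1, hit.ali_start - flank)
    return protein.sequence[start - 1 : hit.env_end]
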