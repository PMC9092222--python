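"""Spike-in-normalized absolute abundance and colonization calling for
defined-community shotgun sequencing (COPRO-Seq).

Reads mapped to each genome are normalized by the genome's informative
(uniquely mappable) size; the known genome equivalents of the spike-in
organisms convert normalized counts into absolute genome equivalents,
which are divided by the sample mass. A strain is called a successful
colonizer when its absolute abundance exceeds the mean distractor-genome
abundance by more than two standard deviations.
"""

from __future__ import annotations

import math

import numpy as np

from .records import CoproseqSample

__all__ = ["absolute_abundance", "colonization_call"]


def absolute_abundance(
    sample: CoproseqSample, combine: str = "arithmetic"
) -> dict[str, float]:
    """Genome equivalents per gram for every non-spike genome.

    Per genome, normalized count n(g) = reads(g) / informative_size(g).
    Each spike-in j with reads yields a scale factor added_j / n(j); the
    factors are combined by arithmetic mean (geometric available via
    ``combine="geometric"``). abundance(g) = n(g) * scale / mass_g, for
    community members and distractors alike.
    """
    scales = []
    for g, added in sample.spike_ins.items():
        reads = sample.reads_per_genome.get(g, 0)
        if reads > 0:
            n = reads / sample.informative_size[g]
            scales.append(added / n)
    if not scales:
        raise ValueError(
            f"sample {sample.sample_id!r}: no spike-in received reads, "
            "no scale factor can be formed"
        )
    if combine == "arithmetic":
        scale = float(np.mean(scales))
    elif combine == "geometric":
        scale = float(math.exp(np.mean(np.log(scales))))
    else:
        raise ValueError(f"unknown combine rule {combine!r}")
    out: dict[str, float] = {}
    for g, reads in sample.reads_per_genome.items():
        if g in sample.spike_ins:
            continue
        n = reads / sample.informative_size[g]
        out[g] = n * scale / sample.mass_g
    return out


def colonization_call(
    abundances: dict[str, float], distractors: set[str]
) -> dict[str, bool]:
    """Call colonization against the distractor noise floor.

    cutoff = mean(distractor abundances) + 2 * sample SD (n-1 denominator);
    a genome is colonized iff its abundance strictly exceeds the cutoff.
    Distractors themselves are never called.
    """
    levels = [abundances[d] for d in sorted(distractors) if d in abundances]
    if len(levels) < 2:
        raise ValueError("need at least 2 distractor abundances to form a cutoff")
    cutoff = float(np.mean(levels)) + 2.0 * float(np.std(levels, ddof=1))
    return {
        g: (a > cutoff)
        for g, a in abundances.items()
        if g not in distractors
    }
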