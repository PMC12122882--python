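"""Reference genome model used by the simulator and coordinate helpers.

The simulator places substitutions uniformly over the 22 autosomes under an
infinite-sites assumption (no recurrence), which is appropriate for the low
burdens studied (tens to a few thousand mutations against ~2.9 Gb of
sequence).  Burdens are reported per *diploid* genome, using the conventional
6.2 Gb constant (2 x 3.1 Gb), so that the duplex call rate per interrogated
single-molecule base scales directly to the reported unit.
"""

from __future__ import annotations

import numpy as np

# Autosome lengths in bp (GRCh37-like, rounded to 1 Mb).
AUTOSOMES: list[tuple[str, int]] = [
    ("1", 249_000_000),
    ("2", 243_000_000),
    ("3", 198_000_000),
    ("4", 191_000_000),
    ("5", 181_000_000),
    ("6", 171_000_000),
    ("7", 159_000_000),
    ("8", 146_000_000),
    ("9", 141_000_000),
    ("10", 136_000_000),
    ("11", 135_000_000),
    ("12", 134_000_000),
    ("13", 115_000_000),
    ("14", 107_000_000),
    ("15", 103_000_000),
    ("16", 90_000_000),
    ("17", 81_000_000),
    ("18", 78_000_000),
    ("19", 59_000_000),
    ("20", 63_000_000),
    ("21", 48_000_000),
    ("22", 51_000_000),
]

#: Haploid length of the modelled genome (sum of autosome lengths).
GENOME_LENGTH: int = sum(length for _, length in AUTOSOMES)

#: Size of a diploid human genome used to report mutation burdens.
DIPLOID_GENOME_SIZE: float = 6.2e9

CHROM_ORDER: dict[str, int] = {name: i for i, (name, _) in enumerate(AUTOSOMES)}

_CUM = np.concatenate([[0], np.cumsum([length for _, length in AUTOSOMES])])

BASES = "ACGT"


def offsets_to_loci(offsets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map linear genome offsets (0-based) to (chromosome, 1-based position)."""
    offsets = np.asarray(offsets, dtype=np.int64)
    if offsets.size and (offsets.min() < 0 or offsets.max() >= GENOME_LENGTH):
        raise ValueError("offset outside the genome model")
    idx = np.searchsorted(_CUM, offsets, side="right") - 1
    chroms = np.array([AUTOSOMES[i][0] for i in idx])
    pos = offsets - _CUM[idx] + 1
    return chroms, pos


def chrom_length(chrom: str) -> int:
    for name, length in AUTOSOMES:
        if name == chrom:
            return length
    raise KeyError(f"unknown chromosome {chrom!r}")
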