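"""Coding gene models and a deterministic toy exome.

A :class:`GeneModel` is a +-strand coding sequence with one flanking base on
each side (so every coding position has a trinucleotide context). For every
possible single-nucleotide change it precomputes the amino-acid consequence
and the folded 96-channel key; the synonymous subset is the selection-free
yardstick for mutation-rate calibration.

The toy exome is a seeded fabrication (synthetic; no real human loci) used by
the simulator and the test suite.
"""

from __future__ import annotations

import dataclasses
import functools
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .channels import CHANNEL_INDEX, pyrimidine_normalize

_CODON_TO_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TO_AA[_stop] = "*"

BASES = ("A", "C", "G", "T")


@dataclasses.dataclass(frozen=True)
class GeneModel:
    """One gene: CDS on the + strand of its own contig, with 1-base flanks."""

    gene: str
    cds: str
    flank5: str = "A"
    flank3: str = "A"

    def __post_init__(self):
        if len(self.cds) % 3 != 0:
            raise ValueError(f"{self.gene}: CDS length not divisible by 3")
        if len(self.flank5) != 1 or len(self.flank3) != 1:
            raise ValueError(f"{self.gene}: flanks must be single bases")
        seq = self.flank5 + self.cds + self.flank3
        if any(b not in BASES for b in seq):
            raise ValueError(f"{self.gene}: invalid base in sequence")

    @property
    def chrom(self) -> str:
        return self.gene

    @property
    def contig_seq(self) -> str:
        return self.flank5 + self.cds + self.flank3

    def genome_pos(self, cds_index: int) -> int:
        """1-based contig position of 0-based CDS index."""
        return cds_index + 2

    @functools.cached_property
    def sites(self) -> pd.DataFrame:
        """Every possible SNV in the CDS, classified exactly once.

        Columns: cds_index (0-based), pos (1-based contig), ref, alt, context
        (+ strand), channel (96-channel index), synonymous, consequence,
        aa_change.
        """
        seq = self.contig_seq
        rows = []
        for i, ref in enumerate(self.cds):
            codon_start = (i // 3) * 3
            codon = self.cds[codon_start : codon_start + 3]
            within = i % 3
            aa_ref = _CODON_TO_AA[codon]
            context = seq[i : i + 3]  # centered on cds index i
            for alt in BASES:
                if alt == ref:
                    continue
                alt_codon = codon[:within] + alt + codon[within + 1 :]
                aa_alt = _CODON_TO_AA[alt_codon]
                synonymous = aa_alt == aa_ref
                if synonymous:
                    consequence = "silent"
                elif aa_alt == "*":
                    consequence = "nonsense"
                else:
                    consequence = "missense"
                key = pyrimidine_normalize(context, ref, alt)
                rows.append(
                    (
                        i, self.genome_pos(i), ref, alt, context,
                        CHANNEL_INDEX[key], synonymous, consequence,
                        f"{aa_ref}{i // 3 + 1}{aa_alt}",
                    )
                )
        return pd.DataFrame(
            rows,
            columns=[
                "cds_index", "pos", "ref", "alt", "context", "channel",
                "synonymous", "consequence", "aa_change",
            ],
        )


def toy_exome(
    n_genes: int = 20,
    seed: int = 777,
    length_range: tuple[int, int] = (300, 3000),
) -> list[GeneModel]:
    """A deterministic synthetic exome: seeded codon sampler, no real loci.

    Each gene starts with ATG, contains no internal stop codons, and ends in a
    stop codon; lengths are drawn uniformly (in codons) within
    ``length_range`` nucleotides.
    """
    rng = np.random.default_rng(seed)
    non_stop = sorted(set(_CODON_TO_AA) - set(standard_dna_table.stop_codons))
    stops = sorted(standard_dna_table.stop_codons)
    models = []
    for g in range(1, n_genes + 1):
        n_codons = int(rng.integers(length_range[0] // 3, length_range[1] // 3 + 1))
        body = [non_stop[i] for i in rng.integers(0, len(non_stop), size=n_codons - 2)]
        cds = "ATG" + "".join(body) + stops[int(rng.integers(0, len(stops)))]
        flank5, flank3 = (BASES[i] for i in rng.integers(0, 4, size=2))
        models.append(GeneModel(gene=f"GENE{g:02d}", cds=cds, flank5=flank5, flank3=flank3))
    return models


def write_exome_fasta(models: Sequence[GeneModel], path: str | Path) -> None:
    """One contig per gene (flank + CDS + flank), 70-column wrapped."""
    with open(path, "w") as fh:
        for m in models:
            fh.write(f">{m.chrom}\n")
            seq = m.contig_seq
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
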