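"""The 96-channel trinucleotide substitution alphabet.

Somatic single-nucleotide variants are conventionally classified by the
substituted pyrimidine (C or T) together with its 5' and 3' flanking bases,
giving 6 substitution types x 16 flank combinations = 96 channels. Variants
reported on the purine strand are folded onto the pyrimidine strand by
reverse complementation, so the 192 raw (trinucleotide, alt) classes map
two-to-one onto the 96 channels.
"""

from __future__ import annotations

from typing import NamedTuple

BASES = ("A", "C", "G", "T")
PYRIMIDINES = ("C", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# COSMIC catalogue ordering: substitution type blocks C>A, C>G, C>T, T>A,
# T>C, T>G; within a block the flanks vary 3'-fastest, alphabetically.
SUBSTITUTION_TYPES = (
    ("C", "A"), ("C", "G"), ("C", "T"),
    ("T", "A"), ("T", "C"), ("T", "G"),
)


class ChannelKey(NamedTuple):
    """A pyrimidine-strand substitution class: 3-mer context plus alternate base."""

    context: str
    alt: str

    @property
    def ref(self) -> str:
        return self.context[1]

    def cosmic_label(self) -> str:
        """Render as the conventional ``A[C>T]G`` string."""
        return f"{self.context[0]}[{self.context[1]}>{self.alt}]{self.context[2]}"


def _enumerate_channels() -> tuple[ChannelKey, ...]:
    keys = []
    for ref, alt in SUBSTITUTION_TYPES:
        for five in BASES:
            for three in BASES:
                keys.append(ChannelKey(five + ref + three, alt))
    return tuple(keys)


CHANNELS: tuple[ChannelKey, ...] = _enumerate_channels()
CHANNEL_INDEX: dict[ChannelKey, int] = {k: i for i, k in enumerate(CHANNELS)}


def complement(base: str) -> str:
    return _COMPLEMENT[base]


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def parse_cosmic_label(label: str) -> ChannelKey:
    """Parse an ``A[C>T]G``-style channel label."""
    if len(label) != 7 or label[1] != "[" or label[3] != ">" or label[5] != "]":
        raise ValueError(f"malformed channel label: {label!r}")
    context = label[0] + label[2] + label[6]
    return ChannelKey(context, label[4])


def pyrimidine_normalize(trinuc_ref: str, ref: str, alt: str) -> ChannelKey:
    """Fold a +-strand (trinucleotide, ref, alt) onto the pyrimidine strand.

    Parameters
    ----------
    trinuc_ref
        3-mer from the + strand of the reference, centered on the variant.
    ref, alt
        Reference and alternate alleles on the + strand; the middle base of
        ``trinuc_ref`` must equal ``ref``.

    Returns
    -------
    ChannelKey
        The pyrimidine-centered channel; identity if ``ref`` is already a
        pyrimidine, otherwise the reverse complement.
    """
    trinuc_ref = trinuc_ref.upper()
    ref = ref.upper()
    alt = alt.upper()
    if len(trinuc_ref) != 3:
        raise ValueError(f"context must be a 3-mer, got {trinuc_ref!r}")
    if trinuc_ref[1] != ref:
        raise ValueError(f"middle of {trinuc_ref!r} is not ref {ref!r}")
    if ref == alt:
        raise ValueError("ref equals alt")
    for b in trinuc_ref + alt:
        if b not in _COMPLEMENT:
            raise ValueError(f"ambiguous or invalid base in {trinuc_ref!r}>{alt!r}")
    if ref in PYRIMIDINES:
        return ChannelKey(trinuc_ref, alt)
    return ChannelKey(reverse_complement(trinuc_ref), complement(alt))


def is_tcw_tkw(key: ChannelKey) -> bool:
    """True for the canonical APOBEC motif: TCW context mutated to a keto base.

    W (weak) is A or T at the 3' flank; K (keto) is T or G as the alternate.
    Exactly 8 of the 96 channels qualify (TCA/TCT contexts x alt T/G).
    """
    ctx = key.context
    return (
        ctx[0] == "T"
        and ctx[1] == "C"
        and ctx[2] in ("A", "T")
        and key.alt in ("T", "G")
    )
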