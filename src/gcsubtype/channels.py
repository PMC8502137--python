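"""The 96 strand-collapsed trinucleotide substitution channels.

Single-base substitutions are reported on the pyrimidine strand: a mutation
whose reference base is a purine (A/G) is reverse-complemented before
tabulation.  Channels are named ``X[R>A]Y`` where ``R`` is the pyrimidine
reference (C or T), ``A`` the alternate base, and ``X``/``Y`` the 5' and 3'
flanking reference bases.  The canonical order — the six substitution types
C>A, C>G, C>T, T>A, T>C, T>G, each expanded over the 16 flanking-base pairs
alphabetically — is fixed so that catalogs are comparable across runs and
against external signature tables.
"""

from __future__ import annotations

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

BASES = ("A", "C", "G", "T")


def _build_channel_order() -> tuple[str, ...]:
    channels = []
    for sub in SUBSTITUTION_TYPES:
        ref = sub[0]
        for five in BASES:
            for three in BASES:
                channels.append(f"{five}[{sub}]{three}")
    return tuple(channels)


CHANNEL_ORDER: tuple[str, ...] = _build_channel_order()

CHANNEL_INDEX: dict[str, int] = {c: i for i, c in enumerate(CHANNEL_ORDER)}


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def channel_of(ref: str, alt: str, context3: str) -> str:
    """Return the pyrimidine-strand channel for one SNV.

    ``context3`` is the reference trinucleotide 5'->3' centered on the
    mutated base.  Purine-reference records are collapsed to the opposite
    strand.  Raises ``ValueError`` when the context center disagrees with
    the reference base or any base is not in ACGT.
    """
    ref, alt, context3 = ref.upper(), alt.upper(), context3.upper()
    if len(ref) != 1 or len(alt) != 1 or len(context3) != 3:
        raise ValueError(f"not a contextualized SNV: {ref}>{alt} in {context3}")
    if any(b not in COMPLEMENT for b in ref + alt + context3):
        raise ValueError(f"non-ACGT base in {ref}>{alt} {context3}")
    if context3[1] != ref:
        raise ValueError(f"context center {context3[1]!r} != ref {ref!r}")
    if ref == alt:
        raise ValueError("ref == alt")
    if ref in ("G", "A"):
        ref, alt, context3 = COMPLEMENT[ref], COMPLEMENT[alt], reverse_complement(context3)
    return f"{context3[0]}[{ref}>{alt}]{context3[2]}"


def parse_channel(channel: str) -> tuple[str, str, str]:
    """Split ``X[R>A]Y`` into (ref, alt, context3)."""
    five, rest = channel[0], channel[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return ref, alt, five + ref + three
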