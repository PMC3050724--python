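"""Packaged mitochondrial reference sequence and base-level lookups.

Haplotypes in this package are difference-coded against the revised
Cambridge Reference Sequence (rCRS, GenBank NC_012920.1, 16,569 bp), the
universal coordinate system of forensic mtDNA work.  The copy shipped here
(``data/synthetic_rcrs.fasta``) is a SYNTHETIC stand-in, not the GenBank
record: positions that the packaged fixtures, motif tree and printed
haplotypes actually touch carry curated, well-attested rCRS bases (the
``CURATED_BASES`` table below); every other position is deterministic
seeded filler at human-mtDNA base composition.  All coordinates are
1-based.
"""

from __future__ import annotations

from functools import lru_cache
from hashlib import md5
from importlib import resources

from Bio import SeqIO

MT_LENGTH = 16569

#: Control region of the circular genome, linearised as two 1-based closed
#: intervals (never a wrapped interval).
CONTROL_REGION = ((16024, 16569), (1, 576))
HVS1 = ((16024, 16365),)
HVS2 = ((73, 340),)

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
IUPAC_AMBIGUITY = frozenset("RYSWKMBDHVN")

#: IUPAC code for each unordered base pair (used when simulating point
#: heteroplasmies and when expanding ambiguity codes).
AMBIGUITY_OF_PAIR = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}

# Well-attested rCRS bases at every position referenced by the packaged
# fixtures: hallmark forensic polymorphisms (73 A>G, 263 A>G, 16189 T>C ...),
# the HVS-I/II C-tracts around 16193, 309/315 and 573, the CP dinucleotide
# 523-524, and the sites used by the curated haplogroup motif tree.
CURATED_BASES: dict[int, str] = {
    # HVS-II and flanking
    61: "C", 62: "G", 64: "C", 73: "A", 103: "G", 125: "T", 143: "G",
    146: "T", 150: "C", 152: "T", 153: "A", 183: "A", 194: "C", 195: "T",
    198: "C", 199: "T", 204: "T", 207: "G", 210: "A", 234: "A", 235: "A",
    247: "G", 249: "A", 263: "A",
    303: "C", 304: "C", 305: "C", 306: "C", 307: "C", 308: "C", 309: "C",
    310: "T", 311: "C", 312: "C", 313: "C", 314: "C", 315: "C", 318: "T",
    374: "A", 489: "T", 499: "G", 523: "A", 524: "C",
    568: "C", 569: "C", 570: "C", 571: "C", 572: "C", 573: "C",
    # HVS-I
    16086: "T", 16092: "T", 16093: "T", 16104: "C", 16111: "C", 16122: "A",
    16124: "T", 16126: "T", 16129: "G", 16131: "T", 16136: "T", 16140: "T",
    16145: "G", 16148: "C", 16160: "A", 16162: "A", 16164: "A", 16167: "C",
    16169: "C", 16172: "T", 16174: "C", 16179: "C", 16181: "A", 16182: "A",
    16183: "A", 16184: "C", 16185: "C", 16186: "C", 16187: "C", 16188: "C",
    16189: "T", 16190: "C", 16191: "C", 16192: "C", 16193: "C", 16195: "T",
    16201: "C", 16203: "A", 16205: "A", 16209: "T", 16213: "G", 16215: "A",
    16217: "T", 16219: "A", 16220: "A", 16222: "C", 16223: "C", 16226: "A",
    16227: "A", 16231: "T", 16232: "C", 16234: "C", 16235: "A", 16236: "C",
    16239: "C", 16241: "A", 16242: "C", 16243: "T", 16248: "C", 16254: "A",
    16257: "C", 16260: "C", 16261: "C", 16263: "T", 16266: "C", 16271: "T",
    16274: "G", 16278: "C", 16289: "A", 16290: "C", 16291: "C", 16294: "C",
    16295: "C", 16296: "C", 16297: "T", 16298: "T", 16300: "A", 16301: "C",
    16302: "A", 16304: "T", 16309: "A", 16311: "T", 16316: "A", 16319: "G",
    16320: "C", 16324: "T", 16325: "T", 16327: "C", 16335: "A", 16342: "T",
    16355: "C", 16356: "T", 16357: "T", 16358: "A", 16360: "C", 16362: "T",
    16390: "G", 16391: "G", 16399: "A", 16468: "T", 16519: "T",
}

_FILL_SEED = 20110218  # fixed: the packaged FASTA must never change
_FILL_COMPOSITION = (("A", 0.309), ("C", 0.313), ("G", 0.131), ("T", 0.247))


def build_synthetic_reference(length: int = MT_LENGTH) -> str:
    """Regenerate the packaged synthetic reference string.

    Deterministic: curated bases are placed first, the remaining positions
    are drawn once from a fixed-seed generator at human-mtDNA base
    composition.  Position 3107 is ``N``, mirroring the placeholder the
    real rCRS keeps for historical numbering.
    """
    import numpy as np

    rng = np.random.default_rng(_FILL_SEED)
    bases, probs = zip(*_FILL_COMPOSITION)
    seq = rng.choice(bases, size=length, p=probs)
    for pos, base in CURATED_BASES.items():
        seq[pos - 1] = base
    seq[3107 - 1] = "N"
    return "".join(seq)


@lru_cache(maxsize=1)
def reference_sequence() -> str:
    """The packaged reference as an uppercase string (index 0 = position 1)."""
    ref = resources.files("mtcrpop.data").joinpath("synthetic_rcrs.fasta")
    with ref.open() as handle:
        record = SeqIO.read(handle, "fasta")
    seq = str(record.seq).upper()
    if len(seq) != MT_LENGTH:
        raise ValueError(f"packaged reference has length {len(seq)}, expected {MT_LENGTH}")
    return seq


def reference_checksum() -> str:
    """MD5 of the packaged reference sequence (uppercase, no header)."""
    return md5(reference_sequence().encode()).hexdigest()


def ref_base(position: int) -> str:
    """Reference base at a 1-based rCRS coordinate."""
    if not 1 <= position <= MT_LENGTH:
        raise ValueError(f"position {position} outside 1..{MT_LENGTH}")
    return reference_sequence()[position - 1]


def transition_partner(base: str) -> str:
    """The transition alternative of a base (A<->G, C<->T)."""
    try:
        return {"A": "G", "G": "A", "C": "T", "T": "C"}[base]
    except KeyError:
        raise ValueError(f"no transition partner for {base!r}") from None


def is_transition(a: str, b: str) -> bool:
    """True if a->b stays within purines or within pyrimidines."""
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)
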