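"""Difference-coded mtDNA control-region haplotypes.

A haplotype is stored as its analysed range(s) plus the set of differences
to the packaged reference, in the forensic notation used by EMPOP-style
population tables:

========  ==========================================================
token     meaning
========  ==========================================================
``263``   transition at 263 (observed base = transition partner of
          the reference base)
``16183C``  substitution to an explicit base (may be a transversion)
``315.1C``  k-th inserted base after a position
``249del``  deletion of the reference base at a position
``523-524del``  deletion range, expanded to one variant per position
``16093Y``  point heteroplasmy, IUPAC ambiguity code
========  ==========================================================

Coordinates are 1-based; the circular genome is linearised, the control
region being the two closed intervals [16024, 16569] and [1, 576].
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

from . import reference as ref

DEL = "DEL"

#: C-insertion anchor positions ignored for haplotype identity, as used for
#: the matching and random-match-probability statistics.
DISREGARD_METHODS = frozenset({16193, 309, 573})
#: Alternative preset (the variant of the rule used for motif-tree figures).
DISREGARD_FIGURE = frozenset({16193, 309, 315})

DISREGARD_PRESETS = {
    "methods": DISREGARD_METHODS,
    "figure": DISREGARD_FIGURE,
}

Interval = tuple[int, int]

_TOKEN_RE = re.compile(
    r"""^(?:
        (?P<delrange>(?P<d1>\d+)-(?P<d2>\d+)del) |
        (?P<del>(?P<dp>\d+)del) |
        (?P<ins>(?P<ip>\d+)\.(?P<ik>\d+)(?P<ib>[ACGT])) |
        (?P<sub>(?P<sp>\d+)(?P<sb>[ACGTRYSWKMBDHV])) |
        (?P<bare>\d+)
    )$""",
    re.VERBOSE,
)


class HaplotypeError(ValueError):
    """Raised for malformed or inconsistent difference-coded input."""


@dataclass(frozen=True, order=True)
class Variant:
    """One difference to the reference at a 1-based coordinate.

    ``insertion_index`` 0 denotes a substitution or deletion at the
    reference position; ``k >= 1`` the k-th inserted base after it
    (315.1C).  ``observed`` is a base, an IUPAC ambiguity code, or ``DEL``.
    """

    position: int
    insertion_index: int = 0
    observed: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.position <= ref.MT_LENGTH:
            raise HaplotypeError(f"position {self.position} outside 1..{ref.MT_LENGTH}")
        if self.insertion_index < 0:
            raise HaplotypeError("insertion_index must be >= 0")
        if self.insertion_index >= 1 and self.observed == DEL:
            raise HaplotypeError("an inserted base cannot be a deletion")
        ok = set("ACGT") | ref.IUPAC_AMBIGUITY | {DEL}
        if self.observed not in ok:
            raise HaplotypeError(f"bad observed state {self.observed!r}")

    @property
    def kind(self) -> str:
        """transition / transversion / insertion / deletion / heteroplasmy."""
        if self.insertion_index >= 1:
            return "insertion"
        if self.observed == DEL:
            return "deletion"
        if self.observed in ref.IUPAC_AMBIGUITY:
            return "heteroplasmy"
        return classify_substitution(self.position, self.observed)

    @property
    def is_insertion(self) -> bool:
        return self.insertion_index >= 1

    def token(self) -> str:
        """Canonical text spelling of the variant."""
        if self.is_insertion:
            return f"{self.position}.{self.insertion_index}{self.observed}"
        if self.observed == DEL:
            return f"{self.position}del"
        if self.observed == ref.transition_partner(ref.ref_base(self.position)):
            return str(self.position)
        return f"{self.position}{self.observed}"


def classify_substitution(position: int, observed: str) -> str:
    """Classify an observed base against the packaged reference.

    Transition when both bases are purines or both pyrimidines, else
    transversion.  The observed base must differ from the reference.
    """
    base = ref.ref_base(position)
    if observed == base:
        raise HaplotypeError(f"{position}{observed} equals the reference base")
    if observed not in "ACGT":
        raise HaplotypeError(f"cannot classify non-base state {observed!r}")
    return "transition" if ref.is_transition(base, observed) else "transversion"


def _validate_ranges(ranges: Sequence[Interval]) -> tuple[Interval, ...]:
    out = []
    for start, end in ranges:
        if not (1 <= start <= end <= ref.MT_LENGTH):
            raise HaplotypeError(f"bad interval {start}-{end}")
        out.append((int(start), int(end)))
    out.sort()
    for (s1, e1), (s2, e2) in zip(out, out[1:]):
        if s2 <= e1:
            raise HaplotypeError(f"overlapping intervals {s1}-{e1} and {s2}-{e2}")
    return tuple(out)


@dataclass(frozen=True)
class Haplotype:
    """A sample's analysed range(s) plus its variant set."""

    sample_id: str
    ranges: tuple[Interval, ...]
    variants: tuple[Variant, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "ranges", _validate_ranges(self.ranges))
        sites = [(v.position, v.insertion_index) for v in self.variants]
        if len(sites) != len(set(sites)):
            raise HaplotypeError(f"{self.sample_id}: duplicate variant site")
        for v in self.variants:
            if not self.covers(v.position):
                raise HaplotypeError(
                    f"{self.sample_id}: variant {v.token()} outside analysed ranges"
                )
        object.__setattr__(self, "variants", tuple(sorted(self.variants)))

    def covers(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.ranges)

    def __iter__(self) -> Iterator[Variant]:
        return iter(self.variants)

    def __len__(self) -> int:
        return len(self.variants)


def parse_tokens(text: str, delimiter: str | None = None) -> list[Variant]:
    """Parse a delimited variant list into :class:`Variant` objects.

    ``delimiter`` of ``None`` splits on whitespace; hyphen-delimited input
    is accepted too, in which case ``523-524del`` range spellings are
    recognised before splitting.
    """
    text = text.strip()
    if not text:
        return []
    if delimiter == "-" or (delimiter is None and "-" in text and " " not in text):
        # hyphen-delimited lists cannot spell deletion ranges: "523del-524del"
        raw = [t for t in text.split("-") if t]
    else:
        # accept the "523-524 del" spelling before splitting on whitespace
        text = re.sub(r"(\d+)-(\d+)\s+del\b", r"\1-\2del", text)
        raw = text.split()
    variants: list[Variant] = []
    for token in raw:
        variants.extend(_parse_one(token))
    return variants


def _parse_one(token: str) -> list[Variant]:
    m = _TOKEN_RE.match(token)
    if not m:
        raise HaplotypeError(f"unrecognised variant token {token!r}")
    if m.group("delrange"):
        lo, hi = int(m.group("d1")), int(m.group("d2"))
        if hi < lo:
            raise HaplotypeError(f"inverted deletion range {token!r}")
        return [Variant(p, 0, DEL) for p in range(lo, hi + 1)]
    if m.group("del"):
        return [Variant(int(m.group("dp")), 0, DEL)]
    if m.group("ins"):
        k = int(m.group("ik"))
        if k < 1:
            raise HaplotypeError(f"insertion index must be >= 1 in {token!r}")
        return [Variant(int(m.group("ip")), k, m.group("ib"))]
    if m.group("sub"):
        pos, base = int(m.group("sp")), m.group("sb")
        _check_position(pos)
        if base in "ACGT" and base == ref.ref_base(pos):
            raise HaplotypeError(f"{token!r} equals the reference base")
        return [Variant(pos, 0, base)]
    pos = int(m.group("bare"))
    _check_position(pos)
    base = ref.ref_base(pos)
    if base not in "ACGT":
        raise HaplotypeError(f"reference base at {pos} is {base!r}; spell the variant explicitly")
    return [Variant(pos, 0, ref.transition_partner(base))]


def _check_position(pos: int) -> None:
    if not 1 <= pos <= ref.MT_LENGTH:
        raise HaplotypeError(f"position {pos} outside 1..{ref.MT_LENGTH}")


def parse_haplotype(
    line: str,
    ranges: Sequence[Interval],
    sample_id: str = "",
    delimiter: str | None = None,
    on_out_of_range: str = "error",
) -> Haplotype:
    """Parse one difference-coded haplotype.

    ``on_out_of_range``: ``"error"`` (default) rejects variants outside the
    declared ranges, ``"drop"`` silently discards them.
    """
    variants = parse_tokens(line, delimiter)
    checked = _validate_ranges(ranges)
    if on_out_of_range == "drop":
        variants = [v for v in variants if any(s <= v.position <= e for s, e in checked)]
    elif on_out_of_range != "error":
        raise ValueError("on_out_of_range must be 'error' or 'drop'")
    return Haplotype(sample_id, checked, tuple(variants))


def serialize(h: Haplotype, delimiter: str = " ") -> str:
    """Canonical spelling: sorted tokens, deletions as ``NNNdel``."""
    return delimiter.join(v.token() for v in h.variants)


def normalize(
    h: Haplotype,
    disregard_insertion_sites: Iterable[int] = DISREGARD_METHODS,
    drop_heteroplasmies: bool = True,
) -> Haplotype:
    """Apply the haplotype-identity conventions.

    C-tract insertions anchored at the disregard sites are removed, and
    (by default) point heteroplasmies are removed entirely, i.e. the
    sample is treated as reference there.  The input is unmodified.
    """
    sites = frozenset(disregard_insertion_sites)
    kept = tuple(
        v
        for v in h.variants
        if not (v.is_insertion and v.position in sites)
        and not (drop_heteroplasmies and v.observed in ref.IUPAC_AMBIGUITY)
    )
    return replace(h, variants=kept)


def intersect_ranges(a: Sequence[Interval], b: Sequence[Interval]) -> tuple[Interval, ...]:
    out = []
    for s1, e1 in a:
        for s2, e2 in b:
            lo, hi = max(s1, s2), min(e1, e2)
            if lo <= hi:
                out.append((lo, hi))
    return tuple(sorted(out))


def restrict(h: Haplotype, window: Sequence[Interval]) -> Haplotype:
    """Trim a haplotype to a common analysis window.

    Variants follow their anchor position; a sample with no overlap cannot
    enter a common-range comparison and raises.
    """
    window = _validate_ranges(window)
    new_ranges = intersect_ranges(h.ranges, window)
    if not new_ranges:
        raise HaplotypeError(f"{h.sample_id}: no overlap with window {window}")
    kept = tuple(
        v for v in h.variants if any(s <= v.position <= e for s, e in new_ranges)
    )
    return replace(h, ranges=new_ranges, variants=kept)


def match_key(
    h: Haplotype,
    window: Sequence[Interval],
    disregard_insertion_sites: Iterable[int] = DISREGARD_METHODS,
    drop_heteroplasmies: bool = True,
) -> str:
    """Canonical identity key of a haplotype over a stated window.

    Two samples are "identical" in the forensic sense iff their keys over
    the same window are equal: restriction, then the disregard rules, then
    a deterministic sorted spelling prefixed by the window.
    """
    restricted = restrict(h, window)
    normal = normalize(restricted, disregard_insertion_sites, drop_heteroplasmies)
    prefix = ",".join(f"{s}-{e}" for s, e in normal.ranges)
    return f"{prefix}|" + "-".join(v.token() for v in normal.variants)
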