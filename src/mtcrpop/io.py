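"""Reading and writing population tables of difference-coded haplotypes.

The table format is TSV with a header and columns ``SampleId``, ``Range``
(space-separated ``start-end`` intervals) and ``Haplotype`` (space- or
hyphen-separated variant tokens).  UTF-8, LF line endings; ``#`` lines are
comments.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .codec import Haplotype, HaplotypeError, Interval, parse_haplotype, serialize

COLUMNS = ("SampleId", "Range", "Haplotype")


@dataclass
class PopulationSample:
    """Named collection of haplotypes with provenance metadata."""

    name: str
    haplotypes: list[Haplotype] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.haplotypes)

    def __iter__(self):
        return iter(self.haplotypes)


def parse_range_field(text: str) -> tuple[Interval, ...]:
    intervals = []
    for part in text.split():
        try:
            start, end = part.split("-")
            intervals.append((int(start), int(end)))
        except ValueError:
            raise HaplotypeError(f"bad range spelling {part!r}") from None
    if not intervals:
        raise HaplotypeError("empty Range field")
    return tuple(intervals)


def format_range_field(ranges: Sequence[Interval]) -> str:
    return " ".join(f"{s}-{e}" for s, e in ranges)


def read_population(
    source, name: str | None = None, on_out_of_range: str = "error"
) -> PopulationSample:
    """Read one population table from a path or text stream."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        handle = path.open(encoding="utf-8")
        close, default_name = True, path.stem
    else:
        handle, close, default_name = source, False, "population"
    pop = PopulationSample(name or default_name)
    try:
        header = None
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if tuple(header[:3]) != COLUMNS:
                    raise HaplotypeError(
                        f"line {lineno}: header must start with {COLUMNS}, got {header[:3]}"
                    )
                continue
            if len(fields) < 2:
                raise HaplotypeError(f"line {lineno}: expected >= 2 columns")
            sample_id = fields[0].strip()
            ranges = parse_range_field(fields[1])
            tokens = fields[2].strip() if len(fields) > 2 else ""
            try:
                hap = parse_haplotype(
                    tokens, ranges, sample_id=sample_id, on_out_of_range=on_out_of_range
                )
            except HaplotypeError as exc:
                raise HaplotypeError(f"line {lineno}: {exc}") from None
            pop.haplotypes.append(hap)
    finally:
        if close:
            handle.close()
    return pop


def validate_population(source) -> list[str]:
    """Per-line error report for a population table (empty when valid)."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    errors: list[str] = []
    header = None
    seen_rows = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            if tuple(header[:3]) != COLUMNS:
                errors.append(f"line {lineno}: bad header {fields[:3]}")
            continue
        seen_rows = True
        try:
            ranges = parse_range_field(fields[1]) if len(fields) > 1 else ()
            parse_haplotype(
                fields[2].strip() if len(fields) > 2 else "",
                ranges,
                sample_id=fields[0].strip(),
            )
        except (HaplotypeError, IndexError) as exc:
            errors.append(f"line {lineno}: {exc}")
    if header is None:
        errors.append("empty file: no header found")
    elif not seen_rows:
        errors.append("no sample rows found")
    return errors


def write_population(pop: PopulationSample, target, comments: Iterable[str] = ()) -> None:
    """Write a population table; `comments` become leading ``#`` lines."""
    if isinstance(target, (str, Path)):
        handle = Path(target).open("w", encoding="utf-8", newline="\n")
        close = True
    else:
        handle, close = target, False
    try:
        for comment in comments:
            handle.write(f"# {comment}\n")
        handle.write("\t".join(COLUMNS) + "\n")
        for hap in pop.haplotypes:
            handle.write(
                f"{hap.sample_id}\t{format_range_field(hap.ranges)}\t{serialize(hap)}\n"
            )
    finally:
        if close:
            handle.close()


def population_from_text(text: str, name: str = "population") -> PopulationSample:
    return read_population(_io.StringIO(text), name=name)
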