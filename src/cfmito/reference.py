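"""Circular mitochondrial reference, control-region annotation and homopolymer runs.

The human mitochondrial genome is a 16,569-bp circular molecule whose
non-coding control region (the D-loop, m.16024-m.576, spanning the origin)
carries the two hypervariable segments HV1 (m.16024-m.16383) and HV2
(m.57-m.372).  Homopolymer runs are the dominant error mode of semiconductor
sequencing, so a maximal-run track over the reference underpins the variant
filters.  All coordinates are 1-based inclusive, matching HGVS ``m.POS``
naming.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

MT_LENGTH = 16_569

#: Fixed control-region annotation (1-based inclusive; D-loop wraps the origin).
D_LOOP = ("D-loop", 16_024, 576, True)
HV1 = ("HV1", 16_024, 16_383, False)
HV2 = ("HV2", 57, 372, False)


@dataclass(frozen=True)
class RegionAnnotation:
    """A named reference region; ``wraps_origin`` marks spans crossing m.16569/m.1."""

    label: str
    start: int
    end: int
    wraps_origin: bool = False

    def contains(self, pos: int) -> bool:
        if self.wraps_origin:
            return pos >= self.start or pos <= self.end
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class HomopolymerRun:
    """A maximal single-nucleotide run. ``start > end`` means the run wraps the origin."""

    start: int
    end: int
    base: str
    run_length: int


@dataclass
class HomopolymerTrack:
    """Maximal homopolymer runs of length >= ``min_len``, sorted by start."""

    min_len: int
    runs: list[HomopolymerRun] = field(default_factory=list)
    _member: dict[int, HomopolymerRun] = field(default_factory=dict, repr=False)
    _adjacent: dict[int, HomopolymerRun] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index()

    def _index(self) -> None:
        self._member.clear()
        self._adjacent.clear()
        for run in self.runs:
            for pos in _run_positions(run):
                self._member[pos] = run
        # indel adjacency: the positions immediately flanking each run
        for run in self.runs:
            for pos in (run.start - 1, run.end + 1):
                if pos in self._member:
                    continue
                self._adjacent.setdefault(pos, run)

    def run_at(self, pos: int, adjacent: bool = False) -> HomopolymerRun | None:
        run = self._member.get(pos)
        if run is None and adjacent:
            run = self._adjacent.get(pos)
        return run

    def to_bed(self, path: str | Path, name: str = "chrM") -> None:
        """Write runs as BED (0-based half-open); wrapped runs emit two intervals."""
        length = max((r.end for r in self.runs if r.end >= r.start), default=MT_LENGTH)
        with open(path, "w") as fh:
            for run in self.runs:
                if run.start <= run.end:
                    fh.write(f"{name}\t{run.start - 1}\t{run.end}\t{run.base}{run.run_length}\n")
                else:
                    fh.write(f"{name}\t{run.start - 1}\t{length}\t{run.base}{run.run_length}\n")
                    fh.write(f"{name}\t0\t{run.end}\t{run.base}{run.run_length}\n")


def _run_positions(run: HomopolymerRun) -> Iterable[int]:
    if run.start <= run.end:
        return range(run.start, run.end + 1)
    # origin-wrapping run: tail of the sequence plus its head
    length = run.start + run.run_length - run.end - 1
    return list(range(run.start, length + 1)) + list(range(1, run.end + 1))


@dataclass(frozen=True)
class MtReference:
    """The mitochondrial reference sequence with fixed region annotations."""

    name: str
    sequence: str
    circular: bool = True
    regions: tuple[RegionAnnotation, ...] = (
        RegionAnnotation(*D_LOOP),
        RegionAnnotation(*HV1),
        RegionAnnotation(*HV2),
    )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Reference base at a 1-based position (wraps on the circular molecule)."""
        if self.circular:
            pos = (pos - 1) % self.length + 1
        if not 1 <= pos <= self.length:
            raise ValueError(f"position {pos} outside reference of length {self.length}")
        return self.sequence[pos - 1]

    def annotate_position(self, pos: int) -> set[str]:
        """Region labels containing ``pos``; {'other'} outside the control region."""
        if not 1 <= pos <= self.length:
            raise ValueError(f"position {pos} outside reference of length {self.length}")
        labels = {r.label for r in self.regions if r.contains(pos)}
        return labels or {"other"}


def load_reference(path: str | Path, circular: bool = True) -> MtReference:
    """Load a single-record FASTA as an :class:`MtReference`.

    Raises ``ValueError`` on an empty file or a multi-record FASTA
    ("ambiguous reference").
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequence records in {path}")
    if len(records) > 1:
        raise ValueError(f"ambiguous reference: {len(records)} records in {path}")
    seq = str(records[0].seq).upper()
    allowed = set("ACGTN")
    if set(seq) - allowed:
        raise ValueError(f"non-nucleotide characters in reference: {sorted(set(seq) - allowed)}")
    return MtReference(name=records[0].id, sequence=seq, circular=circular)


def packaged_reference() -> MtReference:
    """The packaged synthetic 16,569-bp circular mitochondrial reference."""
    with importlib.resources.as_file(
        importlib.resources.files("cfmito") / "data" / "chrM_synthetic.fa"
    ) as p:
        return load_reference(p)


def find_homopolymers(ref: MtReference, min_len: int) -> HomopolymerTrack:
    """All maximal single-nucleotide runs of length >= ``min_len``.

    The scan is linear except that on a circular reference a run touching both
    ends is merged into a single origin-wrapping run (reported with
    ``start > end``).
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    seq = ref.sequence
    n = len(seq)
    runs: list[HomopolymerRun] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and seq[j + 1] == seq[i]:
            j += 1
        runs.append(HomopolymerRun(i + 1, j + 1, seq[i], j - i + 1))
        i = j + 1
    if ref.circular and len(runs) > 1 and runs[0].base == runs[-1].base:
        head, tail = runs[0], runs[-1]
        merged = HomopolymerRun(
            tail.start, head.end, head.base, head.run_length + tail.run_length
        )
        runs = [merged] + runs[1:-1]
    kept = sorted(
        (r for r in runs if r.run_length >= min_len), key=lambda r: r.start
    )
    return HomopolymerTrack(min_len=min_len, runs=kept)


def position_in_run(
    track: HomopolymerTrack, pos: int, variant_type: str, length: int = MT_LENGTH
) -> bool:
    """Whether a variant position falls in (or, for indels, flanks) a run.

    SNVs count only when the position lies inside a run; insertions and
    deletions also count when immediately adjacent to a run boundary, which is
    how left-aligned indels seeded by a run are commonly represented.
    """
    if not 1 <= pos <= length:
        raise ValueError(f"position {pos} outside reference of length {length}")
    adjacent = variant_type in ("del", "ins")
    return track.run_at(pos, adjacent=adjacent) is not None


def run_length_at(track: HomopolymerTrack, pos: int, variant_type: str) -> int:
    """Run length at a position under the same membership rule; 0 if none."""
    run = track.run_at(pos, adjacent=variant_type in ("del", "ins"))
    return run.run_length if run is not None else 0
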