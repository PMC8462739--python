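"""BLAST tabular parsing, best-hit consolidation, and homology breakdowns.

Hits arrive in the standard 12-column tabular format (qseqid, sseqid,
pident, length, mismatch, gapopen, qstart, qend, sstart, send, evalue,
bitscore). Hits with e-value >= the threshold (default 1e-5, strict <) are
discarded; among survivors, one best subject is kept per (query, species)
using a deterministic tie-break chain: max bitscore, then min e-value,
then lexicographically smallest subject id.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .expression import ValidationError

DEFAULT_EVALUE_MAX = 1e-5


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    species_tag: str
    percent_identity: float
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValidationError(f"negative e-value {self.evalue}")
        if not (0 <= self.percent_identity <= 100):
            raise ValidationError(
                f"percent identity {self.percent_identity} outside [0, 100]"
            )


@dataclass(frozen=True)
class BestHit:
    subject_id: str
    evalue: float
    bitscore: float


class HomologyMap:
    """Best hit per (query, species); queries without a survivor are absent."""

    def __init__(self, species_tags: Iterable[str] = ()) -> None:
        self._best: dict[tuple[str, str], BestHit] = {}
        self.species_tags: list[str] = list(species_tags)

    def get(self, query_id: str, species_tag: str) -> BestHit | None:
        return self._best.get((query_id, species_tag))

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._best

    def __len__(self) -> int:
        return len(self._best)

    def items(self):
        return self._best.items()

    def set(self, query_id: str, species_tag: str, hit: BestHit) -> None:
        self._best[(query_id, species_tag)] = hit
        if species_tag not in self.species_tags:
            self.species_tags.append(species_tag)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "query_id": q,
                "species_tag": sp,
                "subject_id": h.subject_id,
                "evalue": h.evalue,
                "bitscore": h.bitscore,
            }
            for (q, sp), h in sorted(self._best.items())
        ]
        return pd.DataFrame(
            rows, columns=["query_id", "species_tag", "subject_id", "evalue", "bitscore"]
        )


Source = Union[str, Path, io.TextIOBase]


def parse_blast_tabular(source: Source, species_tag: str) -> list[HomologyHit]:
    """Parse outfmt-6 style BLAST tabular text into hits.

    Comment lines starting with '#' and blank lines are skipped. Lines with
    fewer than 12 tab-separated fields, or unparseable numeric fields,
    raise :class:`ValidationError` with the 1-based line number. Extra
    columns beyond the canonical 12 are ignored.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            text = fh.read()
    else:
        text = source.read()
    hits: list[HomologyHit] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 12:
            raise ValidationError(
                f"line {lineno}: expected >= 12 tab-separated columns, "
                f"got {len(fields)}"
            )
        try:
            pident = float(fields[2])
            evalue = float(fields[10])
            bitscore = float(fields[11])
        except ValueError as exc:
            raise ValidationError(f"line {lineno}: unparseable numeric field: {exc}")
        hits.append(
            HomologyHit(
                query_id=fields[0],
                subject_id=fields[1],
                species_tag=species_tag,
                percent_identity=pident,
                evalue=evalue,
                bitscore=bitscore,
            )
        )
    return hits


def best_hits(
    hits: Iterable[HomologyHit], evalue_max: float = DEFAULT_EVALUE_MAX
) -> HomologyMap:
    """Filter by e-value (strict <) and keep one best hit per (query, species).

    The result is a deterministic function of the hit multiset: input order
    never affects it.
    """
    hmap = HomologyMap()
    for hit in hits:
        if not hit.evalue < evalue_max:
            continue
        key = (hit.query_id, hit.species_tag)
        incumbent = hmap.get(*key)
        candidate = BestHit(hit.subject_id, hit.evalue, hit.bitscore)
        if incumbent is None or _beats(candidate, incumbent):
            hmap.set(hit.query_id, hit.species_tag, candidate)
        if hit.species_tag not in hmap.species_tags:
            hmap.species_tags.append(hit.species_tag)
    return hmap


def _beats(a: BestHit, b: BestHit) -> bool:
    """True when hit a wins over b: bitscore desc, evalue asc, subject asc."""
    return (-a.bitscore, a.evalue, a.subject_id) < (-b.bitscore, b.evalue, b.subject_id)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, matching printed report style."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GroupBreakdown:
    group_label: str
    n_tsg: int
    both: int
    a_only: int
    b_only: int
    none: int
    pct_homologous: float | None  # None when the group has no TSGs

    def __post_init__(self) -> None:
        if self.both + self.a_only + self.b_only + self.none != self.n_tsg:
            raise ValidationError(
                f"breakdown counts for {self.group_label!r} do not sum to n_tsg"
            )


def homology_breakdown(
    tsg_by_group: Mapping[str, Sequence[str]],
    hmap: HomologyMap,
    species_pair: tuple[str, str],
) -> list[GroupBreakdown]:
    """Classify each group's TSGs by homolog presence in two target species.

    Per group, counts genes with best hits in both species, in species A
    only, in species B only, or in neither, and reports the percentage
    homologous = 100 * (n - none) / n, rounded half-up to one decimal. A
    group with zero TSGs gets zero counts and an undefined (None)
    percentage.
    """
    sp_a, sp_b = species_pair
    out: list[GroupBreakdown] = []
    for group, genes in tsg_by_group.items():
        both = a_only = b_only = none = 0
        for g in genes:
            in_a = hmap.get(g, sp_a) is not None
            in_b = hmap.get(g, sp_b) is not None
            if in_a and in_b:
                both += 1
            elif in_a:
                a_only += 1
            elif in_b:
                b_only += 1
            else:
                none += 1
        n = len(genes)
        pct = round_half_up(100.0 * (n - none) / n) if n else None
        out.append(GroupBreakdown(group, n, both, a_only, b_only, none, pct))
    return out


def breakdown_to_frame(breakdowns: list[GroupBreakdown]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_label": b.group_label,
                "n_tsg": b.n_tsg,
                "both": b.both,
                "a_only": b.a_only,
                "b_only": b.b_only,
                "none": b.none,
                "pct_homologous": b.pct_homologous,
            }
            for b in breakdowns
        ],
        columns=[
            "group_label",
            "n_tsg",
            "both",
            "a_only",
            "b_only",
            "none",
            "pct_homologous",
        ],
    )
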