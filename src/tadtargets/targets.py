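"""TAD-constrained assignment of peaks/genes and direct-vs-indirect calls.

The coordinate frame is a map of disjoint topologically associated domains
(TADs). A candidate gene (already filtered for consistent upregulation on
knockdown) is a *direct* target when the TAD containing its TSS also
contains at least one high-confidence peak of the perturbed repressor, an
*indirect* target when its TAD is peak-free, and *excluded* when its TSS
falls in a boundary gap between TADs.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .intervals import BedParseError, GenomicInterval, Peak, PeakSet


@dataclass(frozen=True)
class TAD:
    interval: GenomicInterval
    tad_id: str


@dataclass
class TADMap:
    """Disjoint TADs; boundary gaps are allowed (genome need not be tiled)."""

    tads: list[TAD]

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[TAD]] = {}
        for t in self.tads:
            by_chrom.setdefault(t.interval.chrom, []).append(t)
        self._by_chrom: dict[str, tuple[list[int], list[TAD]]] = {}
        for chrom, ts in by_chrom.items():
            ts.sort(key=lambda t: t.interval.start)
            for prev, cur in zip(ts, ts[1:]):
                if cur.interval.start < prev.interval.end:
                    raise ValueError(
                        f"overlapping TADs {prev.tad_id} and {cur.tad_id}"
                    )
            self._by_chrom[chrom] = ([t.interval.start for t in ts], ts)

    def __len__(self) -> int:
        return len(self.tads)

    def __iter__(self):
        return iter(self.tads)

    def find(self, chrom: str, pos: int) -> str | None:
        """tad_id of the TAD containing ``pos`` (half-open), else None."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ts = entry
        i = bisect.bisect_right(starts, pos) - 1
        if i >= 0 and ts[i].interval.contains_point(pos):
            return ts[i].tad_id
        return None

    def overlapping(self, iv: GenomicInterval) -> list[str]:
        entry = self._by_chrom.get(iv.chrom)
        if entry is None:
            return []
        _, ts = entry
        return [t.tad_id for t in ts if t.interval.overlaps(iv)]


@dataclass(frozen=True)
class Gene:
    """A stranded gene; the TSS is the start for "+", end-1 for "-"."""

    gene_id: str
    symbol: str
    interval: GenomicInterval

    @property
    def tss(self) -> int:
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass
class TargetCall:
    gene_id: str
    klass: str  # direct | indirect | excluded
    tad_id: str | None = None
    supporting_peaks: list[str] = field(default_factory=list)
    evidence: dict[str, float] = field(default_factory=dict)  # cell line -> log2FC

    def __post_init__(self) -> None:
        if self.klass not in ("direct", "indirect", "excluded"):
            raise ValueError(f"unknown class {self.klass!r}")
        if self.klass == "direct" and not self.supporting_peaks:
            raise ValueError("direct call requires supporting peaks")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_tads(path) -> TADMap:
    """BED4 in: chrom, start, end, tad_id."""
    tads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}: line {lineno}: TAD BED needs 4 columns")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
            tads.append(TAD(iv, fields[3]))
    return TADMap(tads)


def write_tads(tadmap: TADMap, path) -> None:
    with open(path, "w") as fh:
        for t in sorted(tadmap.tads, key=lambda t: (t.interval.chrom, t.interval.start)):
            iv = t.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{t.tad_id}\n")


def read_genes(path) -> list[Gene]:
    """TSV in: gene_id, symbol, chrom, start, end, strand (with header)."""
    genes = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {name: i for i, name in enumerate(header)}
        required = ["gene_id", "symbol", "chrom", "start", "end", "strand"]
        missing = [c for c in required if c not in cols]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if not line.strip():
                continue
            genes.append(
                Gene(
                    f[cols["gene_id"]],
                    f[cols["symbol"]],
                    GenomicInterval(
                        f[cols["chrom"]],
                        int(f[cols["start"]]),
                        int(f[cols["end"]]),
                        f[cols["strand"]],
                    ),
                )
            )
    return genes


def write_genes(genes: Sequence[Gene], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tsymbol\tchrom\tstart\tend\tstrand\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{g.gene_id}\t{g.symbol}\t{iv.chrom}\t{iv.start}\t{iv.end}"
                f"\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Assignment and classification
# ---------------------------------------------------------------------------

def assign_to_tads(
    items: Iterable[Gene] | Iterable[Peak] | PeakSet,
    tads: TADMap,
    anchor: str = "point",
) -> dict[str, str | None]:
    """Map each item's id to the containing tad_id (or None if in a gap).

    Anchor point: TSS for genes, interval midpoint for peaks
    (``anchor="point"``); ``anchor="overlap"`` instead assigns to any TAD
    the full interval overlaps (first by coordinate if several).
    """
    if anchor not in ("point", "overlap"):
        raise ValueError(f"unknown anchor mode {anchor!r}")
    if isinstance(items, PeakSet):
        items = items.peaks
    out: dict[str, str | None] = {}
    for item in items:
        if isinstance(item, Gene):
            key, iv, point = item.gene_id, item.interval, item.tss
        else:
            key, iv, point = item.peak_id, item.interval, item.interval.midpoint
        if anchor == "point":
            out[key] = tads.find(iv.chrom, point)
        else:
            hits = tads.overlapping(iv)
            out[key] = hits[0] if hits else None
    return out


def classify_targets(
    candidate_genes: Sequence[str],
    hc_peaks: PeakSet,
    tads: TADMap,
    genes: Sequence[Gene],
    evidence: dict[str, dict[str, float]] | None = None,
    anchor: str = "point",
) -> list[TargetCall]:
    """Partition candidate genes into direct / indirect / excluded.

    direct: the gene's TAD contains >= 1 high-confidence peak;
    indirect: the gene's TAD contains none; excluded: gene TAD-unassigned.
    ``evidence`` optionally maps gene_id -> {cell line: log2FC}.
    """
    by_id = {g.gene_id: g for g in genes}
    unknown = [gid for gid in candidate_genes if gid not in by_id]
    if unknown:
        raise ValueError(f"unknown gene ids: {unknown}")
    peak_tads = assign_to_tads(hc_peaks, tads, anchor)
    peaks_by_tad: dict[str, list[str]] = {}
    for pid, tid in peak_tads.items():
        if tid is not None:
            peaks_by_tad.setdefault(tid, []).append(pid)
    gene_tads = assign_to_tads(
        [by_id[gid] for gid in candidate_genes], tads, anchor
    )
    calls = []
    for gid in candidate_genes:
        tid = gene_tads[gid]
        ev = (evidence or {}).get(gid, {})
        if tid is None:
            calls.append(TargetCall(gid, "excluded", None, [], ev))
        elif peaks_by_tad.get(tid):
            calls.append(TargetCall(gid, "direct", tid, sorted(peaks_by_tad[tid]), ev))
        else:
            calls.append(TargetCall(gid, "indirect", tid, [], ev))
    return calls


def write_target_calls(calls: Sequence[TargetCall], tsv_path, json_path=None) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("gene_id\tclass\ttad_id\tsupporting_peaks\tevidence\n")
        for c in calls:
            ev = ";".join(f"{k}={v:.6g}" for k, v in sorted(c.evidence.items()))
            fh.write(
                f"{c.gene_id}\t{c.klass}\t{c.tad_id or '.'}\t"
                f"{','.join(c.supporting_peaks) or '.'}\t{ev or '.'}\n"
            )
    if json_path is not None:
        payload = [
            {
                "gene_id": c.gene_id,
                "class": c.klass,
                "tad_id": c.tad_id,
                "supporting_peaks": c.supporting_peaks,
                "evidence": c.evidence,
            }
            for c in calls
        ]
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
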