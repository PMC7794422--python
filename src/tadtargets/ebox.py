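"""E-box (CANNTG) scanning and a presence/absence enrichment test.

The E-box hexamer CANNTG is the consensus bound by basic helix-loop-helix
myogenic factors (MYOD, MYOG, MYF5) and by SNAIL-family repressors; the NN
dinucleotide defines the subtype (e.g. GC for CAGCTG). CANNTG is closed
under reverse complement, so scanning a single strand finds every occupancy
site; subtype labels map pairwise under reverse complement (GC<->GC,
CA<->TG, ...). Enrichment versus background regions is a per-region
presence/absence binomial upper-tail test - a declared simplification of
de novo motif discovery, not a reproduction of it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from scipy import stats

VALID_BASES = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int
    match: str
    subtype: str  # the NN dinucleotide


@dataclass
class EboxEnrichmentResult:
    subtype: str
    fg_with_hit: int
    fg_total: int
    bg_with_hit: int
    bg_total: int
    fold: float
    p: float


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def scan_ebox(
    seq: str, pattern: str = "CANNTG", sequence_id: str = ""
) -> list[MotifHit]:
    """All (possibly overlapping) offsets of a degenerate pattern.

    Pattern letters are A/C/G/T (literal) or N (any of ACGT); an N *in the
    sequence* never matches. Invalid characters raise with their position.
    """
    seq = seq.upper()
    for i, base in enumerate(seq):
        if base not in VALID_BASES:
            raise ValueError(f"invalid character {base!r} at position {i}")
    pattern = pattern.upper()
    k = len(pattern)
    hits = []
    for off in range(len(seq) - k + 1):
        window = seq[off:off + k]
        ok = True
        for p, s in zip(pattern, window):
            if s == "N" or (p != "N" and p != s):
                ok = False
                break
        if ok:
            n_positions = [i for i, p in enumerate(pattern) if p == "N"]
            subtype = "".join(window[i] for i in n_positions)
            hits.append(MotifHit(sequence_id, off, window, subtype))
    return hits


def _has_hit(seq: str, subtype: str, pattern: str) -> bool:
    for hit in scan_ebox(seq, pattern):
        if subtype == "any" or hit.subtype == subtype:
            return True
    return False


def ebox_enrichment(
    fg_seqs: Sequence[str],
    bg_seqs: Sequence[str],
    subtype: str = "any",
    pattern: str = "CANNTG",
) -> EboxEnrichmentResult:
    """Presence/absence enrichment of a motif subtype in foreground regions.

    p = P(X >= fg_with_hit) for X ~ Binomial(fg_total, bg rate); the
    background rate is floored at 1/(bg_total + 1) so a motif absent from
    the background still yields a finite fold.
    """
    if not fg_seqs:
        raise ValueError("foreground set is empty")
    if not bg_seqs:
        raise ValueError("background set is empty")
    fg_with = sum(_has_hit(s, subtype, pattern) for s in fg_seqs)
    bg_with = sum(_has_hit(s, subtype, pattern) for s in bg_seqs)
    bg_rate = max(bg_with / len(bg_seqs), 1.0 / (len(bg_seqs) + 1))
    fg_rate = fg_with / len(fg_seqs)
    p = float(stats.binom.sf(fg_with - 1, len(fg_seqs), bg_rate))
    return EboxEnrichmentResult(
        subtype, fg_with, len(fg_seqs), bg_with, len(bg_seqs),
        fold=fg_rate / bg_rate, p=p,
    )


def extract_sequences(fasta_path, intervals) -> list[str]:
    """Fetch interval sequences from a FASTA genome (requires pyfaidx)."""
    from pyfaidx import Fasta

    genome = Fasta(str(fasta_path))
    return [str(genome[iv.chrom][iv.start:iv.end]) for iv in intervals]


def write_hits_bed(hits: Sequence[MotifHit], intervals, path) -> None:
    """Hits as BED6 (name = subtype); offsets are relative to each interval."""
    by_id = {f"seq{i}": iv for i, iv in enumerate(intervals)}
    with open(path, "w") as fh:
        for hit in hits:
            iv = by_id.get(hit.sequence_id)
            if iv is None:
                continue
            start = iv.start + hit.offset
            fh.write(
                f"{iv.chrom}\t{start}\t{start + len(hit.match)}\t"
                f"{hit.subtype}\t0\t+\n"
            )
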