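"""Assembly- and annotation-level statistics.

Covers contiguity metrics (N50, GC), telomeric-end classification with the
derived chromosome-number estimate, per-window coding density, and the
gene/intron/intergenic/UTR summary metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import (
    GeneModel,
    Interval,
    SequenceRecord,
    ValidationError,
    as_contig_map,
    revcomp,
    total_length,
)


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    total_len: int
    gc_percent: float
    n50: int
    largest: int


@dataclass(frozen=True)
class TelomereCall:
    contig_id: str
    five_prime: bool
    three_prime: bool
    units_5: int
    units_3: int

    @property
    def n_ends(self) -> int:
        return int(self.five_prime) + int(self.three_prime)


@dataclass(frozen=True)
class ChromosomeEstimate:
    n_both: int
    n_one: int
    point: float
    low: int
    high: int


def n50(lengths: Iterable[int]) -> int:
    """Smallest length L such that contigs >= L hold >= half the assembly."""
    lens = sorted(lengths, reverse=True)
    if not lens:
        raise ValidationError("empty assembly")
    half = sum(lens) / 2
    acc = 0
    for ln in lens:
        acc += ln
        if acc >= half:
            return ln
    return lens[-1]  # pragma: no cover


def gc_percent(seqs: Iterable[str]) -> float:
    """GC over unambiguous (non-N) bases only, in percent."""
    gc = at = 0
    for s in seqs:
        s = s.upper()
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    if gc + at == 0:
        return 0.0
    return 100.0 * gc / (gc + at)


def assembly_stats(contigs: Sequence[SequenceRecord]) -> AssemblyStats:
    if not contigs:
        raise ValidationError("empty assembly")
    lens = [len(c) for c in contigs]
    return AssemblyStats(
        n_contigs=len(contigs),
        total_len=sum(lens),
        gc_percent=gc_percent(c.seq for c in contigs),
        n50=n50(lens),
        largest=max(lens),
    )


def _max_tandem_run(seq: str, unit: str, window: int, max_mismatch: int) -> int:
    """Longest run of consecutive copies of ``unit`` starting in the first
    ``window`` bases, allowing up to ``max_mismatch`` mismatches over the run."""
    ulen = len(unit)
    best = 0
    limit = min(window, len(seq) - ulen + 1)
    for start in range(max(limit, 0)):
        mism = 0
        n = 0
        i = start
        while i + ulen <= len(seq):
            d = sum(a != b for a, b in zip(seq[i:i + ulen], unit))
            if mism + d > max_mismatch:
                break
            mism += d
            n += 1
            i += ulen
        if n > best:
            best = n
    return best


def detect_telomeric_ends(
    contig: SequenceRecord | str,
    unit: str = "TTAGGG",
    min_units: int = 5,
    search_window: int = 1000,
    max_mismatch: int = 2,
) -> TelomereCall:
    """Classify each contig end as telomeric or not.

    An end is telomeric when at least ``min_units`` tandem copies of the
    repeat unit (or its reverse complement) start within ``search_window``
    bases of that end, with at most ``max_mismatch`` mismatches across the
    whole run.  The 3' end is scanned on the reverse complement, which makes
    the call exactly symmetric under reverse-complementing the contig.
    """
    if len(unit) < 4:
        raise ValidationError("telomere unit must be at least 4 bp")
    if search_window < min_units * len(unit):
        raise ValidationError("search window shorter than the minimal run")
    if isinstance(contig, SequenceRecord):
        cid, seq = contig.id, contig.seq
    else:
        cid, seq = "contig", contig.upper()
    rc_unit = revcomp(unit)
    units5 = max(
        _max_tandem_run(seq, unit, search_window, max_mismatch),
        _max_tandem_run(seq, rc_unit, search_window, max_mismatch),
    )
    tail = revcomp(seq)
    units3 = max(
        _max_tandem_run(tail, unit, search_window, max_mismatch),
        _max_tandem_run(tail, rc_unit, search_window, max_mismatch),
    )
    five = units5 >= min_units
    three = units3 >= min_units
    return TelomereCall(
        contig_id=cid,
        five_prime=five,
        three_prime=three,
        units_5=units5 if five else 0,
        units_3=units3 if three else 0,
    )


def classify_assembly_telomeres(
    contigs: Sequence[SequenceRecord], **kwargs
) -> tuple[list[TelomereCall], int, int]:
    """Telomere calls for every contig plus (n_both_ends, n_one_end) counts."""
    calls = [detect_telomeric_ends(c, **kwargs) for c in contigs]
    n_both = sum(1 for c in calls if c.n_ends == 2)
    n_one = sum(1 for c in calls if c.n_ends == 1)
    return calls, n_both, n_one


def estimate_chromosomes(n_both: int, n_one: int) -> ChromosomeEstimate:
    """Chromosome-number estimate from telomere-capped contig counts.

    Each both-ends-capped contig is one complete chromosome; each one-end
    contig contributes one chromosome end, i.e. half a chromosome:
    ``point = n_both + n_one / 2``.  The reported range rounds the point
    estimate outward to multiples of ten, mirroring the loose phrasing such
    estimates are quoted with; the point estimate is the scientific output.
    """
    if n_both < 0 or n_one < 0:
        raise ValidationError("contig counts must be non-negative")
    point = n_both + n_one / 2
    low = int(math.floor(point / 10) * 10)
    high = int(math.ceil(point / 10) * 10)
    return ChromosomeEstimate(n_both, n_one, point, low, high)


def coding_density(
    models: Iterable[GeneModel],
    contig_lengths: Mapping[str, int],
    window: int = 5000,
) -> tuple[pd.DataFrame, pd.Series]:
    """Fraction of each fixed window covered by the union of CDS intervals.

    Windows tile each contig from its first base; the final partial window is
    kept with its true length.  Returns the per-window table and the
    per-contig mean coverage fraction (CDS bases / contig length).
    """
    if window <= 0:
        raise ValidationError("window must be positive")
    coverage = {
        cid: np.zeros(ln, dtype=bool) for cid, ln in contig_lengths.items()
    }
    for m in models:
        if m.contig_id not in coverage:
            raise ValidationError(
                f"{m.locus_tag}: unknown contig {m.contig_id}"
            )
        cov = coverage[m.contig_id]
        for iv in m.cds:
            cov[iv.start - 1: iv.end] = True
    rows = []
    means = {}
    for cid, cov in coverage.items():
        ln = len(cov)
        for start in range(0, ln, window):
            end = min(start + window, ln)
            frac = float(cov[start:end].mean()) if end > start else 0.0
            rows.append((cid, start + 1, end, frac))
        means[cid] = float(cov.mean()) if ln else 0.0
    df = pd.DataFrame(
        rows, columns=["contig", "window_start", "window_end", "fraction"]
    )
    return df, pd.Series(means, name="mean_cds_fraction")


def gene_metrics(
    models: Sequence[GeneModel], contigs=None
) -> dict[str, float]:
    """Annotation summary metrics.

    Gene length is the genomic span (first to last exon base, introns and
    UTRs included).  Intergenic length is the gap between consecutive gene
    spans on a contig (overlapping or abutting genes contribute no gap).
    Intron GC requires the genome and is NaN without it.
    """
    n_genes = len(models)
    out: dict[str, float] = {"n_genes": n_genes}
    if n_genes == 0:
        return out
    out["mean_gene_length"] = float(
        np.mean([len(m.span) for m in models])
    )
    # intergenic gaps per contig
    by_contig: dict[str, list[Interval]] = {}
    for m in models:
        by_contig.setdefault(m.contig_id, []).append(m.span)
    gaps = []
    for spans in by_contig.values():
        spans.sort()
        for a, b in zip(spans, spans[1:]):
            if b.start > a.end + 1:
                gaps.append(b.start - a.end - 1)
    out["mean_intergenic_length"] = float(np.mean(gaps)) if gaps else 0.0

    introns = [iv for m in models for iv in m.introns()]
    out["n_introns"] = len(introns)
    out["introns_per_gene"] = len(introns) / n_genes
    out["mean_intron_length"] = (
        float(np.mean([len(iv) for iv in introns])) if introns else 0.0
    )
    if contigs is not None and introns:
        cmap = as_contig_map(contigs)
        seqs = []
        for m in models:
            contig = cmap[m.contig_id]
            seqs.extend(contig[iv.start - 1: iv.end] for iv in m.introns())
        out["intron_gc_percent"] = gc_percent(seqs)
    else:
        out["intron_gc_percent"] = float("nan")

    for kind in ("utr5", "utr3"):
        with_utr = [m for m in models if getattr(m, kind)]
        out[f"n_genes_with_{kind}"] = len(with_utr)
        out[f"mean_{kind}_length"] = (
            float(np.mean([total_length(getattr(m, kind)) for m in with_utr]))
            if with_utr else 0.0
        )
        out[f"n_introns_in_{kind}"] = sum(
            _introns_in_utr(m, kind) for m in models
        )
    return out


def _introns_in_utr(model: GeneModel, kind: str) -> int:
    """Introns whose two flanking exon bases both lie inside that UTR."""
    utr_bases = set()
    for iv in getattr(model, kind):
        utr_bases.update((iv.start, iv.end))
        utr_bases.update(range(iv.start, iv.end + 1))
    n = 0
    for g in model.introns():
        if (g.start - 1) in utr_bases and (g.end + 1) in utr_bases:
            n += 1
    return n


def stats_table(stats: AssemblyStats, n_both: int, n_one: int,
                metrics: Mapping[str, float]) -> pd.DataFrame:
    est = estimate_chromosomes(n_both, n_one)
    rows = [
        ("n_contigs", stats.n_contigs),
        ("total_length_bp", stats.total_len),
        ("gc_percent", round(stats.gc_percent, 2)),
        ("n50_bp", stats.n50),
        ("largest_contig_bp", stats.largest),
        ("contigs_both_telomeric_ends", n_both),
        ("contigs_one_telomeric_end", n_one),
        ("chromosome_point_estimate", est.point),
        ("chromosome_range_low", est.low),
        ("chromosome_range_high", est.high),
    ]
    rows += [(k, v) for k, v in metrics.items()]
    return pd.DataFrame(rows, columns=["metric", "value"])
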