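"""UTR characterisation: full-length 3'UTR selection, terminal k-mer
enrichment against a dinucleotide-shuffle null, positional profiles around
the cleavage site, U-content profiles, and the Kozak position-frequency
matrix around the start codon.

RNA is stored as T internally; reports convert to U for display only.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import (
    GeneModel,
    Interval,
    ValidationError,
    as_contig_map,
    spliced_seq,
)
from .genome_stats import gc_percent


@dataclass
class UtrRecord:
    gene_tag: str
    kind: str                  # five_prime | three_prime
    seq: str
    introns: int = 0
    full_length: bool = False

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class PositionalProfile:
    anchor: str                # cleavage_site | start_codon
    positions: list[int]
    values: list[float]
    peak_position: int | None = None
    peak_value: float = 0.0
    half_window: tuple[int, int] | None = None


@dataclass
class MotifResult:
    kmer: str
    observed: int
    expected: float
    sd: float
    z_score: float
    peak_position: int | None = None
    peak_probability: float = 0.0

    @property
    def kmer_rna(self) -> str:
        return self.kmer.replace("T", "U")


def extract_utrs(
    models: Sequence[GeneModel], contigs
) -> list[UtrRecord]:
    """Spliced UTR sequences (transcript orientation) for every annotated UTR."""
    cmap = as_contig_map(contigs)
    out = []
    for m in models:
        for kind, attr in (("five_prime", "utr5"), ("three_prime", "utr3")):
            ivs = getattr(m, attr)
            if not ivs:
                continue
            seq = spliced_seq(cmap, m, attr)
            introns = _introns_within(m, ivs)
            out.append(UtrRecord(m.locus_tag, kind, seq, introns))
    return out


def _introns_within(model: GeneModel, ivs: Sequence[Interval]) -> int:
    n = 0
    lo, hi = ivs[0].start, ivs[-1].end
    for g in model.introns():
        if lo <= g.start and g.end <= hi:
            n += 1
    return n


def flag_full_length_3utr(
    models: Sequence[GeneModel],
    reads: pd.DataFrame,
    tolerance: int = 0,
) -> set[str]:
    """Genes whose 3'UTR is confirmed full-length by a read boundary.

    A 3'UTR counts as full-length iff at least one read's polyA/oligo-dT
    boundary lies within ``tolerance`` bases of the annotated UTR end and
    that same read's alignment covers the whole UTR span.
    """
    by_tag = {m.locus_tag: m for m in models}
    unknown = set(reads["gene"]) - set(by_tag)
    if unknown:
        raise ValidationError(f"reads reference unknown gene(s): {sorted(unknown)[:5]}")
    flagged: set[str] = set()
    for gene, grp in reads.groupby("gene"):
        m = by_tag[gene]
        if not m.utr3:
            continue
        lo, hi = m.utr3[0].start, m.utr3[-1].end
        end_coord = hi if m.strand == "+" else lo
        ok = (
            (grp["aln_start"] <= lo) & (grp["aln_end"] >= hi)
            & ((grp["polya_boundary"] - end_coord).abs() <= tolerance)
        )
        if bool(ok.any()):
            flagged.add(gene)
    return flagged


def terminal_window(
    utrs: Iterable[UtrRecord], window: int = 100
) -> list[tuple[str, str, bool]]:
    """Last ``window`` bases of each 3'UTR; shorter records kept whole and
    marked.  Returns (gene_tag, tail_sequence, is_short) tuples."""
    if window <= 0:
        raise ValidationError("window must be positive")
    out = []
    for u in utrs:
        if u.kind != "three_prime":
            continue
        short = u.length < window
        out.append((u.gene_tag, u.seq[-window:], short))
    return out


# ---------------------------------------------------------------------------
# dinucleotide-preserving shuffle (Altschul-Erickson)

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Random permutation of ``seq`` preserving its dinucleotide counts."""
    n = len(seq)
    if n < 3 or len(set(seq)) == 1:
        return seq
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    verts = [v for v in edges if v != last]
    last_edge: dict[str, str] = {}
    for _ in range(200):
        last_edge = {
            v: edges[v][int(rng.integers(len(edges[v])))] for v in verts
        }

        def reaches(v: str) -> bool:
            seen = set()
            while v != last:
                if v in seen or v not in last_edge:
                    return False
                seen.add(v)
                v = last_edge[v]
            return True

        if all(reaches(v) for v in verts):
            break
    else:  # pragma: no cover - rejection sampling essentially always succeeds
        return seq
    walk_order: dict[str, list[str]] = {}
    for v, outs in edges.items():
        rest = list(outs)
        if v in last_edge:
            rest.remove(last_edge[v])
        perm = rng.permutation(len(rest))
        rest = [rest[i] for i in perm]
        if v in last_edge:
            rest.append(last_edge[v])
        walk_order[v] = rest
    res = [seq[0]]
    ptr: dict[str, int] = defaultdict(int)
    v = seq[0]
    while True:
        outs = walk_order.get(v, [])
        i = ptr[v]
        if i >= len(outs):
            break
        ptr[v] += 1
        v = outs[i]
        res.append(v)
    assert len(res) == n
    return "".join(res)


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def kmer_enrichment(
    seqs: Sequence[str],
    k: int = 6,
    n_shuffles: int = 100,
    seed: int = 0,
) -> list[MotifResult]:
    """Rank k-mers by per-sequence occurrence against a shuffle null.

    ``observed`` counts sequences containing the k-mer at least once; the
    null mean and sd come from ``n_shuffles`` dinucleotide-preserving
    shuffles of every sequence.  Ranked by z descending, ties by observed
    count then lexicographic k-mer.
    """
    seqs = [s.upper().replace("U", "T") for s in seqs]
    if len(seqs) < 20:
        raise ValidationError("k-mer enrichment needs at least 20 sequences")
    if k < 4:
        raise ValidationError("k must be >= 4")
    if all(len(s) < k for s in seqs):
        raise ValidationError("all sequences shorter than k")
    obs = Counter()
    for s in seqs:
        obs.update(_kmer_set(s, k))
    rng = np.random.default_rng(seed)
    sums: dict[str, float] = defaultdict(float)
    sumsq: dict[str, float] = defaultdict(float)
    for _ in range(n_shuffles):
        cnt = Counter()
        for s in seqs:
            cnt.update(_kmer_set(dinucleotide_shuffle(s, rng), k))
        for km, c in cnt.items():
            sums[km] += c
            sumsq[km] += c * c
    results = []
    for km in set(obs) | set(sums):
        mean = sums[km] / n_shuffles
        var = max(sumsq[km] / n_shuffles - mean * mean, 0.0)
        sd = float(np.sqrt(var))
        o = obs.get(km, 0)
        if sd > 0:
            z = (o - mean) / sd
        else:
            z = float("inf") if o > mean else 0.0
        results.append(MotifResult(km, o, mean, sd, z))
    results.sort(key=lambda r: (-r.z_score, -r.observed, r.kmer))
    return results


def positional_profile(
    tails: Sequence[str],
    kmer: str,
    upstream: int = 100,
    count_mode: str = "first",
) -> PositionalProfile:
    """Occurrence-start profile of a k-mer anchored at the cleavage site.

    Sequences are the last <= ``upstream`` bases of each 3'UTR; the base
    just before the cleavage site is position -1.  ``count_mode`` 'first'
    counts each sequence once at its leftmost occurrence (zero-or-one per
    sequence); 'all' counts every occurrence.  Reports the argmax position
    and the smallest window holding >= 50 % of the counted occurrences.
    """
    kmer = kmer.upper().replace("U", "T")
    k = len(kmer)
    positions = list(range(-upstream, 0))
    counts = np.zeros(upstream)
    n = len(tails)
    for s in tails:
        s = s.upper().replace("U", "T")
        hits = [i for i in range(len(s) - k + 1) if s[i:i + k] == kmer]
        if count_mode == "first":
            hits = hits[:1]
        for i in hits:
            p = i - len(s)
            if -upstream <= p <= -1:
                counts[p + upstream] += 1
    values = counts / n if n else counts
    prof = PositionalProfile("cleavage_site", positions, values.tolist())
    total = counts.sum()
    if total == 0:
        warnings.warn(f"k-mer {kmer} absent from all sequences")
        return prof
    imax = int(np.argmax(counts))
    prof.peak_position = positions[imax]
    prof.peak_value = float(values[imax])
    best = None
    half = total / 2
    csum = np.concatenate([[0.0], np.cumsum(counts)])
    for w in range(1, upstream + 1):
        for s in range(upstream - w + 1):
            if csum[s + w] - csum[s] >= half:
                best = (positions[s], positions[s + w - 1])
                break
        if best:
            break
    prof.half_window = best
    return prof


def u_profile(tails: Sequence[str], upstream: int = 100) -> PositionalProfile:
    """Mean U(T) content per position relative to the cleavage site."""
    counts = np.zeros(upstream)
    cover = np.zeros(upstream)
    for s in tails:
        s = s.upper().replace("U", "T")
        L = min(len(s), upstream)
        for j in range(1, L + 1):
            counts[upstream - j] += s[-j] == "T"
            cover[upstream - j] += 1
    with np.errstate(invalid="ignore"):
        vals = np.where(cover > 0, counts / np.maximum(cover, 1), 0.0)
    return PositionalProfile(
        "cleavage_site", list(range(-upstream, 0)), vals.tolist()
    )


# ---------------------------------------------------------------------------
# Kozak context

_IUPAC = {
    frozenset("A"): "a", frozenset("C"): "c", frozenset("G"): "g",
    frozenset("T"): "t",
    frozenset("AG"): "r", frozenset("CT"): "y", frozenset("CG"): "s",
    frozenset("AT"): "w", frozenset("GT"): "k", frozenset("AC"): "m",
    frozenset("CGT"): "b", frozenset("AGT"): "d", frozenset("ACT"): "h",
    frozenset("ACG"): "v", frozenset("ACGT"): "n",
}


@dataclass
class KozakResult:
    matrix: pd.DataFrame       # rows A/C/G/T, columns positions
    consensus: str
    n_used: int
    n_excluded: int
    upstream_at_fraction: float


def kozak_matrix(
    models: Sequence[GeneModel],
    contigs,
    flank: int = 10,
    restrict_to: set[str] | None = None,
) -> KozakResult:
    """Position-frequency matrix of the start-codon context.

    Uses ``flank`` bases of 5'UTR immediately upstream of ATG plus the start
    codon and ``flank`` coding bases; genes whose spliced 5'UTR (or CDS) is
    too short are excluded and counted.  Columns are position-stochastic.
    The consensus letter is the base with frequency >= 0.4 (upper case for a
    majority base), else the IUPAC code of all bases >= 0.25, else 'n'.
    """
    cmap = as_contig_map(contigs)
    cols = list(range(-flank, 0)) + list(range(1, flank + 4))
    counts = pd.DataFrame(0.0, index=list("ACGT"), columns=cols)
    n_used = n_excluded = 0
    for m in models:
        if restrict_to is not None and m.locus_tag not in restrict_to:
            continue
        if not m.utr5 or not m.cds:
            n_excluded += 1
            continue
        u5 = spliced_seq(cmap, m, "utr5")
        cds = spliced_seq(cmap, m, "cds")
        if len(u5) < flank or len(cds) < flank + 3:
            n_excluded += 1
            continue
        context = u5[-flank:] + cds[:flank + 3]
        if any(c not in "ACGT" for c in context):
            n_excluded += 1
            continue
        for col, base in zip(cols, context):
            counts.loc[base, col] += 1
        n_used += 1
    if n_used:
        freq = counts / n_used
    else:
        freq = counts
    consensus = []
    for col in cols:
        column = freq[col]
        top = column.idxmax()
        if column[top] >= 0.4:
            consensus.append(top)
        else:
            present = frozenset(column.index[column >= 0.25])
            consensus.append(_IUPAC.get(present, "n") if present else "n")
    upstream = freq[[c for c in cols if c < 0]]
    at = float(upstream.loc[["A", "T"]].sum(axis=0).mean()) if n_used else 0.0
    return KozakResult(freq, "".join(consensus), n_used, n_excluded, at)


def utr_stats(utrs: Sequence[UtrRecord], bin_width: int = 25) -> dict:
    """Counts, mean lengths, 25 bp length histograms, intron counts and
    3'UTR GC for a set of UTR records."""
    out: dict = {}
    for kind in ("five_prime", "three_prime"):
        recs = [u for u in utrs if u.kind == kind]
        key = "utr5" if kind == "five_prime" else "utr3"
        out[f"n_{key}"] = len(recs)
        lengths = [u.length for u in recs]
        out[f"mean_{key}_length"] = float(np.mean(lengths)) if recs else 0.0
        out[f"n_introns_in_{key}"] = sum(u.introns for u in recs)
        if recs:
            edges = np.arange(0, max(lengths) + bin_width, bin_width)
            hist, _ = np.histogram(lengths, bins=edges)
            out[f"{key}_length_hist"] = {
                int(edges[i]): int(h) for i, h in enumerate(hist) if h
            }
        else:
            out[f"{key}_length_hist"] = {}
    three = [u.seq for u in utrs if u.kind == "three_prime"]
    out["utr3_gc_percent"] = gc_percent(three) if three else 0.0
    return out


def profiles_table(
    tails: Sequence[str], motifs: Sequence[str], upstream: int = 100
) -> pd.DataFrame:
    """Tidy per-position table of motif occurrence profiles plus U content."""
    data = {"position": list(range(-upstream, 0))}
    for motif in motifs:
        prof = positional_profile(tails, motif, upstream)
        data[f"motif_prob_{motif.replace('T', 'U')}"] = prof.values
    data["u_content"] = u_profile(tails, upstream).values
    return pd.DataFrame(data)
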