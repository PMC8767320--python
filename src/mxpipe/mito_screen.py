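"""Composite mitochondrial-hallmark protein screen.

Five evidence channels over one proteome: reciprocal best hits against a
mitochondrial reference database (e <= 0.001), dual targeting-signal
consensus (both predictors > 0.5), a tail-anchor filter (TMD within 32 aa
of the C-terminus), the beta-signal / beta-barrel outer-membrane-protein
(MBOMP) scan with secondary-structure filters, and an HMM-hit join.  The
external predictors themselves are never run — their tabular outputs are
inputs; a Kyte-Doolittle hydropathy fallback can stand in for a missing TMD
table so the pipeline runs end-to-end, but it is not equivalent to a real
TMD predictor.  The screen never auto-declares a mitochondrial protein:
flagged candidates get verdict ``manual_review``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import HitRecord, PipelineConfig, SequenceRecord, ValidationError


@dataclass(frozen=True)
class TmdInterval:
    protein_id: str
    start: int
    end: int
    source: str = "external_table"

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValidationError(
                f"{self.protein_id}: bad TMD {self.start}..{self.end}"
            )


@dataclass(frozen=True)
class BetaSignalHit:
    protein_id: str
    start: int                  # 1-based position of the 8-mer
    residues: str
    primary: bool = False


@dataclass(frozen=True)
class ResidueClasses:
    """Po/Hy residue classes of the beta-signal pattern Po-x-G-Hy-x-Hy-x-Hy.

    The defaults are this package's declared choice; the original class
    tables are not restated in the study this screen models.
    """

    polar: frozenset = frozenset("DEHKNQRST")
    hydrophobic: frozenset = frozenset("AFILMVWY")

    def __post_init__(self):
        if not self.polar or not self.hydrophobic:
            raise ValidationError("residue classes must be non-empty")


@dataclass
class CandidateEvidence:
    protein_id: str
    rbh: bool = False
    hmm_hit: bool = False
    targeting_consensus: bool = False
    tail_anchor: bool = False
    mbomp: bool = False
    details: dict = field(default_factory=dict)

    @property
    def any_flag(self) -> bool:
        return any((self.rbh, self.hmm_hit, self.targeting_consensus,
                    self.tail_anchor, self.mbomp))

    @property
    def verdict(self) -> str:
        return "manual_review" if self.any_flag else "rejected"


# ---------------------------------------------------------------------------
# reciprocal best hits

def _best_hits(hits: Iterable[HitRecord], evalue_max: float) -> dict[str, HitRecord]:
    """Best hit per query: lowest e-value, ties by higher bitscore then
    lexicographic subject id.  Hits above the threshold are ignored."""
    best: dict[str, HitRecord] = {}
    for h in hits:
        if h.evalue > evalue_max:
            continue
        cur = best.get(h.query)
        if cur is None or (h.evalue, -h.bitscore, h.subject) < (
            cur.evalue, -cur.bitscore, cur.subject
        ):
            best[h.query] = h
    return best


def reciprocal_best_hits(
    fwd: Sequence[HitRecord],
    rev: Sequence[HitRecord],
    evalue_max: float = 0.001,
) -> list[tuple[str, str]]:
    """Mutual best-hit pairs (query, subject) with both e-values <= cutoff."""
    fbest = _best_hits(fwd, evalue_max)
    rbest = _best_hits(rev, evalue_max)
    pairs = []
    for q, h in fbest.items():
        back = rbest.get(h.subject)
        if back is not None and back.subject == q:
            pairs.append((q, h.subject))
    return sorted(pairs)


# ---------------------------------------------------------------------------
# targeting-signal consensus

def targeting_consensus(
    scores_a: Mapping[str, float],
    scores_b: Mapping[str, float],
    threshold: float = 0.5,
    proteome: Iterable[str] | None = None,
) -> tuple[set[str], float]:
    """Proteins with strictly > ``threshold`` probability from both
    predictors, plus the flagged percentage (one decimal) of the proteome.

    Missing scores count as 0.  The rate denominator is the supplied
    proteome when given, otherwise the union of scored proteins.
    """
    for scores in (scores_a, scores_b):
        bad = [p for p, v in scores.items() if not 0 <= v <= 1]
        if bad:
            raise ValidationError(f"probability outside [0,1] for {bad[:5]}")
    universe = set(proteome) if proteome is not None else (
        set(scores_a) | set(scores_b)
    )
    flagged = {
        p for p in universe
        if scores_a.get(p, 0.0) > threshold and scores_b.get(p, 0.0) > threshold
    }
    rate = round(100.0 * len(flagged) / len(universe), 1) if universe else 0.0
    return flagged, rate


def scores_to_map(df: pd.DataFrame, tool: str) -> dict[str, float]:
    """Column view of a long (protein_id, tool, probability) score table."""
    sub = df[df["tool"] == tool]
    return dict(zip(sub["protein_id"], sub["probability"].astype(float)))


# ---------------------------------------------------------------------------
# tail anchor

def tail_anchor_filter(
    protein_lengths: Mapping[str, int],
    tmds: Sequence[TmdInterval],
    window: int = 32,
) -> set[str]:
    """Proteins with a TMD ending within ``window`` aa of the C-terminus
    (distance = length - TMD end, inclusive <=)."""
    kept = set()
    for t in tmds:
        if t.protein_id not in protein_lengths:
            raise ValidationError(f"TMD for unknown protein {t.protein_id}")
        ln = protein_lengths[t.protein_id]
        if t.end > ln:
            raise ValidationError(
                f"{t.protein_id}: TMD end {t.end} beyond length {ln}"
            )
        if ln - t.end <= window:
            kept.add(t.protein_id)
    return kept


_KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}


def hydropathy_tmd_fallback(
    protein: SequenceRecord | str,
    window: int = 19,
    threshold: float = 1.6,
) -> list[TmdInterval]:
    """Plumbing fallback TMD caller from Kyte-Doolittle hydropathy.

    Maximal runs of residue positions whose centred ``window``-mean
    hydropathy is >= ``threshold``; labelled ``hydropathy_fallback`` so
    downstream reports can tell it from a real predictor's output.
    """
    if isinstance(protein, SequenceRecord):
        pid, seq = protein.id, protein.seq
    else:
        pid, seq = "protein", protein.upper()
    n = len(seq)
    if n < window:
        return []
    vals = np.array([_KYTE_DOOLITTLE.get(c, 0.0) for c in seq])
    means = np.convolve(vals, np.ones(window) / window, mode="valid")
    half = window // 2
    hot = means >= threshold          # centre positions half .. n-half-1
    intervals = []
    i = 0
    while i < len(hot):
        if hot[i]:
            j = i
            while j + 1 < len(hot) and hot[j + 1]:
                j += 1
            intervals.append(TmdInterval(
                pid, i + half + 1, j + half + 1, "hydropathy_fallback"
            ))
            i = j + 1
        else:
            i += 1
    return intervals


# ---------------------------------------------------------------------------
# beta-signal / MBOMP

def beta_signal_scan(
    protein: SequenceRecord | str,
    classes: ResidueClasses | None = None,
    cterm_window: int = 15,
) -> list[BetaSignalHit]:
    """All C-terminal 8-mers matching Po-x-G-Hy-x-Hy-x-Hy.

    A hit's last residue must lie within ``cterm_window`` residues of the
    C-terminus; the rightmost hit is marked primary.
    """
    classes = classes or ResidueClasses()
    if isinstance(protein, SequenceRecord):
        pid, seq = protein.id, protein.seq
    else:
        pid, seq = "protein", protein.upper()
    n = len(seq)
    hits = []
    for start in range(max(0, n - cterm_window - 8), n - 7):
        w = seq[start:start + 8]
        if n - (start + 8) > cterm_window:
            continue
        if (w[0] in classes.polar and w[2] == "G"
                and w[3] in classes.hydrophobic
                and w[5] in classes.hydrophobic
                and w[7] in classes.hydrophobic):
            hits.append(BetaSignalHit(pid, start + 1, w))
    if hits:
        hits[-1] = BetaSignalHit(pid, hits[-1].start, hits[-1].residues, True)
    return hits


@dataclass(frozen=True)
class MbompResult:
    passed: bool
    strand_fraction: float
    helix_fraction: float
    signal_helix_fraction: float
    context_length: int


def mbomp_filter(
    protein: SequenceRecord | str,
    hit: BetaSignalHit,
    ss: SequenceRecord | str,
    config: PipelineConfig | None = None,
) -> MbompResult:
    """Secondary-structure filters over the context preceding a beta-signal.

    Pass iff the <= 300 aa window immediately before the motif has strand
    fraction >= 25 % and helix fraction <= 10 %, and at most 50 % of the 8
    motif residues are helical.  Boundary cases pass (>= / <= semantics).
    """
    config = config or PipelineConfig()
    pseq = protein.seq if isinstance(protein, SequenceRecord) else protein
    sstr = ss.seq if isinstance(ss, SequenceRecord) else ss.upper()
    if len(sstr) != len(pseq):
        raise ValidationError(
            "secondary-structure string length differs from protein length"
        )
    ctx_start = max(0, hit.start - 1 - config.mbomp_context)
    ctx = sstr[ctx_start: hit.start - 1]
    motif_ss = sstr[hit.start - 1: hit.start - 1 + config.beta_signal_len]
    if not ctx:
        return MbompResult(False, 0.0, 0.0, 0.0, 0)
    e_frac = ctx.count("E") / len(ctx)
    h_frac = ctx.count("H") / len(ctx)
    sig_h = motif_ss.count("H") / config.beta_signal_len
    passed = (
        e_frac >= config.mbomp_min_strand
        and h_frac <= config.mbomp_max_helix
        and sig_h <= config.mbomp_max_signal_helix
    )
    return MbompResult(passed, e_frac, h_frac, sig_h, len(ctx))


def mbomp_screen(
    proteins: Sequence[SequenceRecord],
    ss3: Sequence[SequenceRecord],
    classes: ResidueClasses | None = None,
    config: PipelineConfig | None = None,
) -> set[str]:
    """Proteins whose primary beta-signal passes the MBOMP filters."""
    config = config or PipelineConfig()
    ss_by_id = {r.id: r for r in ss3}
    out = set()
    for p in proteins:
        if len(p.seq) < config.beta_signal_len:
            continue
        hits = beta_signal_scan(p, classes, config.beta_cterm_window)
        ss = ss_by_id.get(p.id)
        if ss is None:
            continue
        for h in hits:
            if mbomp_filter(p, h, ss, config).passed:
                out.add(p.id)
                break
    return out


# ---------------------------------------------------------------------------
# HMM join and aggregation

def hmm_candidate_join(
    hmm_hits: pd.DataFrame,
    db_hits: pd.DataFrame,
    evalue_max: float = 0.001,
) -> pd.DataFrame:
    """Proteins with >= 1 HMM hit, annotated with database-homolog presence.

    Duplicate (protein, profile) rows are collapsed.  Returns a frame with
    protein, n_profiles, best_evalue, has_db_homolog.
    """
    if hmm_hits.empty:
        return pd.DataFrame(
            columns=["protein", "n_profiles", "best_evalue", "has_db_homolog"]
        )
    dedup = hmm_hits.drop_duplicates(subset=["protein", "profile"])
    grouped = dedup.groupby("protein").agg(
        n_profiles=("profile", "nunique"), best_evalue=("evalue", "min")
    ).reset_index()
    if db_hits is not None and not db_hits.empty:
        good = set(db_hits.loc[db_hits["evalue"] <= evalue_max, "protein"])
    else:
        good = set()
    grouped["has_db_homolog"] = grouped["protein"].isin(good)
    return grouped.sort_values("protein").reset_index(drop=True)


def aggregate_report(
    proteome_ids: Sequence[str],
    rbh_pairs: Sequence[tuple[str, str]] = (),
    hmm_candidates: Iterable[str] = (),
    targeting_ids: Iterable[str] = (),
    tail_anchor_ids: Iterable[str] = (),
    mbomp_ids: Iterable[str] = (),
) -> tuple[pd.DataFrame, dict]:
    """One evidence row per protein plus per-channel summary counts.

    Any flagged protein gets verdict ``manual_review`` — final calls are a
    manual step by design — and unflagged proteins are ``rejected``.
    Percentages are of the whole proteome, one decimal.
    """
    universe = list(proteome_ids)
    uset = set(universe)
    channels = {
        "rbh": {q for q, _ in rbh_pairs},
        "hmm_hit": set(hmm_candidates),
        "targeting_consensus": set(targeting_ids),
        "tail_anchor": set(tail_anchor_ids),
        "mbomp": set(mbomp_ids),
    }
    for name, members in channels.items():
        unknown = members - uset
        if unknown:
            raise ValidationError(
                f"channel {name} references unknown protein(s): "
                f"{sorted(unknown)[:5]}"
            )
    rows = []
    for pid in universe:
        ev = CandidateEvidence(
            pid,
            rbh=pid in channels["rbh"],
            hmm_hit=pid in channels["hmm_hit"],
            targeting_consensus=pid in channels["targeting_consensus"],
            tail_anchor=pid in channels["tail_anchor"],
            mbomp=pid in channels["mbomp"],
        )
        rows.append((pid, ev.rbh, ev.hmm_hit, ev.targeting_consensus,
                     ev.tail_anchor, ev.mbomp, ev.verdict))
    df = pd.DataFrame(rows, columns=[
        "protein_id", "rbh", "hmm_hit", "targeting_consensus",
        "tail_anchor", "mbomp", "verdict",
    ])
    n = len(universe)
    union = set().union(*channels.values()) if channels else set()
    summary = {"n_proteins": n, "union": len(union)}
    for name, members in channels.items():
        summary[f"n_{name}"] = len(members)
        summary[f"pct_{name}"] = round(100.0 * len(members) / n, 1) if n else 0.0
    summary["pct_union"] = round(100.0 * len(union) / n, 1) if n else 0.0
    return df, summary
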