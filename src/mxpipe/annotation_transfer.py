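"""Clustering-verified annotation transfer between assemblies.

The transfer engine decides, per old gene, whether its model survived the
move to the new assembly: staged clustering at 100 % then 95 % identity
(both with a strict equal-length rule, after cd-hit ``-s 1``) marks models
as transferred; coordinate overlap on the new assembly then identifies
fusion and split events among the leftovers, which are renamed with the
``fu``/``p`` locus-tag convention.  External mappers are never run — their
candidate gene models are inputs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align

from .io_core import (
    GeneModel,
    Interval,
    PipelineConfig,
    ValidationError,
    total_length,
)

STAGES = ("denovo_evm", "ratt", "gmap", "pasa", "manual")
EXACT_STAGES = frozenset({"denovo_evm", "ratt"})

OUTCOMES = (
    "transferred", "fused", "split", "failed", "contaminant",
    "opposite_strand_conflict", "duplicate_collapsed", "poor_isoform",
)
_FAIL_OUTCOMES = frozenset(OUTCOMES[3:])


@dataclass
class TransferRecord:
    old_tag: str
    outcome: str
    stage: str | None
    new_tags: list[str] = field(default_factory=list)
    note: str = ""

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise ValidationError(f"unknown outcome {self.outcome!r}")
        if self.outcome == "transferred" and len(self.new_tags) != 1:
            raise ValidationError(
                f"{self.old_tag}: transferred needs exactly one new tag"
            )
        if self.outcome == "split" and len(self.new_tags) < 2:
            raise ValidationError(f"{self.old_tag}: split needs >=2 new tags")


@dataclass(frozen=True)
class ClusterParams:
    identity: float = 1.0
    require_equal_length: bool = True

    def __post_init__(self):
        if not 0 < self.identity <= 1:
            raise ValidationError("identity must be in (0, 1]")


@dataclass
class ClusterResult:
    clusters: list[frozenset]          # members are (origin, tag) pairs
    transferred: dict[str, str]        # old tag -> matched new tag
    duplicated: set[str] = field(default_factory=set)


def _check_unique(seqs: Mapping[str, str], origin: str) -> None:
    # Mapping keys are unique by construction; guard against non-mapping input
    if not isinstance(seqs, Mapping):
        tags = [t for t, _ in seqs]
        dup = {t for t in tags if tags.count(t) > 1}
        if dup:
            raise ValidationError(f"duplicate {origin} tag(s): {sorted(dup)}")


def cluster_exact(
    old_seqs: Mapping[str, str], new_seqs: Mapping[str, str]
) -> ClusterResult:
    """Co-cluster sequences that are identical (same length, 100 % identity).

    Old tags that fall in a mixed-origin cluster are transferred; when one
    old sequence matches several identical new copies the duplication is
    noted.  Purely order-independent: clusters are keyed by sequence string.
    """
    _check_unique(old_seqs, "old")
    _check_unique(new_seqs, "new")
    by_seq: dict[str, list[tuple[str, str]]] = {}
    for tag, seq in old_seqs.items():
        by_seq.setdefault(seq, []).append(("old", tag))
    for tag, seq in new_seqs.items():
        by_seq.setdefault(seq, []).append(("new", tag))
    clusters, transferred, duplicated = [], {}, set()
    for members in by_seq.values():
        clusters.append(frozenset(members))
        news = sorted(t for o, t in members if o == "new")
        olds = [t for o, t in members if o == "old"]
        if news and olds:
            for t in olds:
                transferred[t] = news[0]
                if len(news) > 1:
                    duplicated.add(t)
    clusters.sort(key=lambda c: sorted(c))
    return ClusterResult(clusters, transferred, duplicated)


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = 0
_aligner.open_gap_score = -2
_aligner.extend_gap_score = -1


def global_identity(a: str, b: str) -> float:
    """Identity of the best-scoring global alignment: matches / columns.

    Scoring: match +1, mismatch 0, gap open -2, gap extend -1.
    """
    if a == b:
        return 1.0
    aln = _aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def cluster_near(
    old_seqs: Mapping[str, str],
    new_seqs: Mapping[str, str],
    identity: float = 0.95,
) -> ClusterResult:
    """Co-cluster equal-length sequences with global identity >= threshold.

    Clusters are single-linkage components within each length class; an old
    tag is transferred to its best-identity new partner (ties broken by tag).
    """
    _check_unique(old_seqs, "old")
    _check_unique(new_seqs, "new")
    members = [("old", t, s) for t, s in old_seqs.items()]
    members += [("new", t, s) for t, s in new_seqs.items()]
    by_len: dict[int, list[int]] = {}
    for i, (_, _, s) in enumerate(members):
        by_len.setdefault(len(s), []).append(i)

    parent = list(range(len(members)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    transferred: dict[str, str] = {}
    best: dict[str, tuple[float, str]] = {}
    for idxs in by_len.values():
        for ai in range(len(idxs)):
            for bi in range(ai + 1, len(idxs)):
                i, j = idxs[ai], idxs[bi]
                ident = global_identity(members[i][2], members[j][2])
                if ident >= identity:
                    union(i, j)
                    oi, ti, _ = members[i]
                    oj, tj, _ = members[j]
                    if oi != oj:
                        old_t = ti if oi == "old" else tj
                        new_t = tj if oi == "old" else ti
                        cur = best.get(old_t)
                        # higher identity wins; ties -> lexicographically
                        # smaller new tag, for order invariance
                        if cur is None or ident > cur[0] or (
                            ident == cur[0] and new_t < cur[1]
                        ):
                            best[old_t] = (ident, new_t)
    comp: dict[int, set] = {}
    for i, (origin, tag, _) in enumerate(members):
        comp.setdefault(find(i), set()).add((origin, tag))
    clusters = sorted(
        (frozenset(c) for c in comp.values()), key=lambda c: sorted(c)
    )
    transferred = {t: nt for t, (_, nt) in best.items()}
    duplicated = set()
    for c in comp.values():
        news = [t for o, t in c if o == "new"]
        olds = [t for o, t in c if o == "old"]
        if len(news) > 1:
            duplicated.update(set(olds) & set(transferred))
    return ClusterResult(clusters, transferred, duplicated)


# ---------------------------------------------------------------------------
# Fusion / split detection on the new coordinate system

@dataclass(frozen=True)
class FusionEvent:
    old_tags: tuple[str, ...]
    new_tag: str


@dataclass(frozen=True)
class SplitEvent:
    old_tag: str
    new_tags: tuple[str, ...]


def _cds_overlap(a: Sequence[Interval], b: Sequence[Interval]) -> int:
    ov = 0
    for x in a:
        for y in b:
            lo, hi = max(x.start, y.start), min(x.end, y.end)
            if hi >= lo:
                ov += hi - lo + 1
    return ov


def detect_fusion_split(
    old_models: Sequence[GeneModel],
    new_models: Sequence[GeneModel],
    min_frac: float = 0.5,
) -> tuple[list[FusionEvent], list[SplitEvent]]:
    """Identify fusion and split events by CDS overlap on shared coordinates.

    A new model whose CDS covers >= ``min_frac`` of the CDS of two or more
    old models (same contig and strand) is a fusion; one old model covering
    >= ``min_frac`` of the CDS of two or more new models is a split.  Events
    are disjoint: any model implicated in both raises a conflict error.
    """
    by_loc_new: dict[tuple[str, str], list[GeneModel]] = {}
    for m in new_models:
        by_loc_new.setdefault((m.contig_id, m.strand), []).append(m)
    fused_partners: dict[str, list[str]] = {}
    split_partners: dict[str, list[str]] = {}
    for om in old_models:
        for nm in by_loc_new.get((om.contig_id, om.strand), []):
            if not om.span.overlaps(nm.span):
                continue
            ov = _cds_overlap(om.cds, nm.cds)
            if not ov:
                continue
            if ov >= min_frac * total_length(om.cds):
                fused_partners.setdefault(nm.locus_tag, []).append(om.locus_tag)
            if ov >= min_frac * total_length(nm.cds):
                split_partners.setdefault(om.locus_tag, []).append(nm.locus_tag)

    new_by_tag = {m.locus_tag: m for m in new_models}
    old_by_tag = {m.locus_tag: m for m in old_models}
    fusions = [
        FusionEvent(tuple(sorted(olds)), new_tag)
        for new_tag, olds in sorted(fused_partners.items())
        if len(olds) >= 2
    ]
    splits = [
        SplitEvent(
            old_tag,
            tuple(sorted(
                news, key=lambda t: new_by_tag[t].span.start
            )),
        )
        for old_tag, news in sorted(split_partners.items())
        if len(news) >= 2
    ]
    in_fusion = {t for ev in fusions for t in ev.old_tags}
    in_fusion |= {ev.new_tag for ev in fusions}
    in_split = {ev.old_tag for ev in splits}
    in_split |= {t for ev in splits for t in ev.new_tags}
    conflict = in_fusion & in_split
    if conflict:
        raise ValidationError(
            f"models in overlapping fusion and split events: {sorted(conflict)}"
        )
    return fusions, splits


_TAG_RE = re.compile(r"^(?P<prefix>.+_)(?P<num>\d+)$")


def _tag_number(tag: str) -> tuple[str, int]:
    m = _TAG_RE.match(tag)
    if not m:
        raise ValidationError(f"locus tag {tag!r} does not match PREFIX_number")
    return m.group("prefix"), int(m.group("num"))


def fusion_name(old_tags: Iterable[str]) -> str:
    """``PREFIX_a`` + ``PREFIX_b`` -> ``PREFIX_afub`` (numeric order)."""
    parsed = sorted(_tag_number(t) for t in old_tags)
    prefixes = {p for p, _ in parsed}
    if len(prefixes) != 1:
        raise ValidationError(f"mixed prefixes in fusion: {sorted(prefixes)}")
    prefix = prefixes.pop()
    nums = [n for _, n in parsed]
    return prefix + "fu".join(str(n) for n in nums)


def split_names(old_tag: str, k: int) -> list[str]:
    """``PREFIX_n`` split into k parts -> ``PREFIX_np1`` ... ``PREFIX_npk``."""
    prefix, num = _tag_number(old_tag)
    return [f"{prefix}{num}p{i}" for i in range(1, k + 1)]


def assign_locus_tags(
    fusions: Sequence[FusionEvent],
    splits: Sequence[SplitEvent],
    new_models: Sequence[GeneModel],
) -> dict[str, str]:
    """Mapping new-assembly tag -> renamed tag under the fu/p convention.

    Split parts are numbered in ascending plus-strand coordinate order (the
    SplitEvent already carries them so ordered).  Untouched tags map to
    themselves.
    """
    rename = {m.locus_tag: m.locus_tag for m in new_models}
    for ev in fusions:
        rename[ev.new_tag] = fusion_name(ev.old_tags)
    for ev in splits:
        for part, new_tag in zip(
            split_names(ev.old_tag, len(ev.new_tags)), ev.new_tags
        ):
            rename[new_tag] = part
    return rename


# ---------------------------------------------------------------------------
# Staged transfer engine

def run_transfer(
    old_seqs: Mapping[str, str],
    stage_candidates: Mapping[str, Mapping[str, str]],
    config: PipelineConfig | None = None,
    mapped_old_models: Sequence[GeneModel] | None = None,
    new_models: Sequence[GeneModel] | None = None,
    old_categories: Mapping[str, str] | None = None,
) -> list[TransferRecord]:
    """Staged clustering-verified transfer of old gene models.

    ``old_seqs`` maps old locus tags to CDS nucleotide strings;
    ``stage_candidates`` maps stage names (a subset of
    denovo_evm/ratt/gmap/pasa/manual, processed in that order) to candidate
    CDS maps from that mapper's output.  The first two stages demand exact
    identity, later stages near identity (>= ``cluster_near_identity``).
    After all stages, fusion and split events are detected by coordinate
    overlap when ``mapped_old_models`` (old models lifted onto the new
    coordinate system) and ``new_models`` are supplied.  Whatever remains is
    failed, with the category from ``old_categories`` when provided.
    """
    config = config or PipelineConfig()
    unknown = set(stage_candidates) - set(STAGES)
    if unknown:
        raise ValidationError(f"unknown stage(s): {sorted(unknown)}")
    records: dict[str, TransferRecord] = {}
    pool = dict(old_seqs)
    for stage in STAGES:
        if stage not in stage_candidates or not pool:
            continue
        cands = stage_candidates[stage]
        if stage in EXACT_STAGES:
            res = cluster_exact(pool, cands)
        else:
            res = cluster_near(pool, cands, config.cluster_near_identity)
        for old_tag, new_tag in res.transferred.items():
            note = "duplicated_in_new" if old_tag in res.duplicated else ""
            records[old_tag] = TransferRecord(
                old_tag, "transferred", stage, [new_tag], note
            )
            del pool[old_tag]

    if pool and mapped_old_models is not None and new_models is not None:
        pending = [m for m in mapped_old_models if m.locus_tag in pool]
        fusions, splits = detect_fusion_split(
            pending, new_models, config.fusion_overlap_frac
        )
        for ev in fusions:
            name = fusion_name(ev.old_tags)
            for t in ev.old_tags:
                if t in pool:
                    records[t] = TransferRecord(t, "fused", "manual", [name])
                    del pool[t]
        for ev in splits:
            names = split_names(ev.old_tag, len(ev.new_tags))
            if ev.old_tag in pool:
                records[ev.old_tag] = TransferRecord(
                    ev.old_tag, "split", "manual", names
                )
                del pool[ev.old_tag]

    old_categories = old_categories or {}
    for tag in sorted(pool):
        category = old_categories.get(tag, "failed")
        outcome = category if category in _FAIL_OUTCOMES else "failed"
        records[tag] = TransferRecord(tag, outcome, None, [], category)
    return [records[t] for t in old_seqs if t in records]


def transfer_summary(records: Sequence[TransferRecord]) -> dict:
    """Outcome/stage counts with a conservation check.

    Raises when any old tag appears more than once — that signals a
    bookkeeping bug upstream, never a data property.
    """
    tags = [r.old_tag for r in records]
    if len(set(tags)) != len(tags):
        dup = sorted({t for t in tags if tags.count(t) > 1})
        raise ValidationError(f"old tag(s) recorded twice: {dup}")
    by_outcome = {o: 0 for o in OUTCOMES}
    by_stage: dict[str, int] = {}
    fused_models, split_models = set(), set()
    for r in records:
        by_outcome[r.outcome] += 1
        if r.stage:
            by_stage[r.stage] = by_stage.get(r.stage, 0) + 1
        if r.outcome == "fused":
            fused_models.update(r.new_tags)
        elif r.outcome == "split":
            split_models.update(r.new_tags)
    total = len(records)
    assert sum(by_outcome.values()) == total  # conservation by construction
    return {
        "total_old_tags": total,
        "by_outcome": by_outcome,
        "by_stage": by_stage,
        "fused_old_tags": by_outcome["fused"],
        "fusion_models": len(fused_models),
        "split_old_tags": by_outcome["split"],
        "split_models": len(split_models),
        "transfer_rate": by_outcome["transferred"] / total if total else 0.0,
    }


def records_frame(records: Sequence[TransferRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.old_tag, r.outcome, r.stage or "", ",".join(r.new_tags), r.note)
            for r in records
        ],
        columns=["old_tag", "outcome", "stage", "new_tags", "note"],
    )
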