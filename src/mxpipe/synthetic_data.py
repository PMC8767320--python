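"""Seeded synthetic genomes, assembly pairs, transcript evidence and proteomes.

Every artifact the pipeline consumes can be generated here with a
machine-readable ground-truth manifest, so each analysis stage is testable
by recovery of planted features rather than against downloaded data.  One
integer seed drives everything; fixed per-artifact sub-streams keep the
outputs byte-identical for identical (spec, seed) and independently
regenerable.

Planted structure mirrors the study conditions this pipeline models:
telomere-capped contigs, AT-rich UTRs with AATAAA-family polyadenylation
signals 20-30 bp upstream of the cleavage site inside U-rich flanks, an
"old"/"new" assembly pair with known fusion/split/frameshift events, and a
proteome with planted targeting-consensus, tail-anchor and beta-signal
positives plus single-violation decoys.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import (
    GeneModel,
    HitRecord,
    Interval,
    SequenceRecord,
    ValidationError,
    cds_sequences,
    revcomp,
    total_length,
    translate,
    write_fasta,
    write_gff3,
    write_hits,
)


class SizingError(ValueError):
    """Requested synthetic content does not fit the requested layout."""


_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    "".join(c) for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in _STOPS
]
_AA20 = "ACDEFGHIKLMNPQRSTVWY"
POLAR = "DEHKNQRST"
HYDROPHOBIC = "AFILMVWY"

READ_COLUMNS = ["read_id", "gene", "contig", "aln_start", "aln_end",
                "polya_boundary"]
SCORE_COLUMNS = ["protein_id", "tool", "probability"]
TMD_COLUMNS = ["protein_id", "start", "end", "source"]
HMM_COLUMNS = ["protein", "profile", "evalue"]
DB_COLUMNS = ["protein", "db_subject", "evalue"]


@dataclass
class SynthesisSpec:
    """Parameters of the synthetic study corpus.

    Defaults are the generator's standing study conditions: telomere unit
    TTAGGG with 12 copies per capped end, ~1.95 introns per gene, mean
    3'UTR 312 bp and 5'UTR 62 bp, hexamer AATAAA planted 20-30 bp upstream
    of the cleavage site in 80 % of genes with U-rich 10 bp flanks,
    genome GC 37.2 % (introns 27.6 %, 3'UTR GC 26.1 %, AT-rich 5'UTRs),
    and a proteome of 4665 proteins carrying 24 dual-targeting, 7
    tail-anchor and 2 beta-barrel positives among decoys.
    """

    seed: int = 0
    # genome
    n_contigs: int = 8
    n_both_telomeres: int = 2
    n_one_telomere: int = 3
    telomere_unit: str = "TTAGGG"
    telomere_units_per_end: int = 12
    n_genes: int = 120
    intron_rate: float = 1.95
    utr5_mean_len: int = 62
    utr3_mean_len: int = 312
    polya_motif: str = "AATAAA"
    polya_offset_range: tuple[int, int] = (20, 30)
    polya_plant_fraction: float = 0.8
    u_rich_flank: bool = True
    full_length_fraction: float = 0.7
    gc_background: float = 0.372
    intron_gc: float = 0.276
    utr3_gc: float = 0.261
    utr5_at: float = 0.7
    mean_intergenic: int = 1855
    max_contig_len: int | None = None
    # assembly-pair events
    n_fusion_events: int = 5
    n_split_events: int = 3
    n_frameshift_events: int = 2
    n_contaminant_genes: int = 2
    # proteome
    n_proteins: int = 4665
    n_targeting_pos: int = 24
    n_targeting_decoy: int = 40
    n_ta_pos: int = 7
    n_ta_decoy: int = 10
    n_mbomp_pos: int = 2
    n_mbomp_decoy: int = 6
    n_rbh_pairs: int = 50
    n_noise_hits: int = 60
    n_hmm_hits: int = 28
    n_hmm_with_homolog: int = 6
    locus_prefix: str = "MONOS_"

    def validate(self) -> None:
        counts = [
            self.n_contigs, self.n_both_telomeres, self.n_one_telomere,
            self.n_genes, self.n_fusion_events, self.n_split_events,
            self.n_frameshift_events, self.n_contaminant_genes,
            self.n_proteins, self.n_targeting_pos, self.n_targeting_decoy,
            self.n_ta_pos, self.n_ta_decoy, self.n_mbomp_pos,
            self.n_mbomp_decoy, self.n_rbh_pairs, self.n_hmm_hits,
        ]
        if any(c < 0 for c in counts):
            raise ValidationError("negative count in synthesis spec")
        if self.n_both_telomeres + self.n_one_telomere > self.n_contigs:
            raise ValidationError("more telomeric contigs than contigs")
        lo, hi = self.polya_offset_range
        if not (len(self.polya_motif) <= lo <= hi <= 100):
            raise ValidationError("polyA offsets must lie within the tail window")
        if not 0 <= self.polya_plant_fraction <= 1:
            raise ValidationError("plant fraction outside [0,1]")
        if not 0 <= self.full_length_fraction <= 1:
            raise ValidationError("full-length fraction outside [0,1]")
        if len(self.telomere_unit) < 4:
            raise ValidationError("telomere unit too short")
        if self.n_hmm_with_homolog > self.n_hmm_hits:
            raise ValidationError("hmm-with-homolog exceeds hmm hits")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def _rand_seq(rng: np.random.Generator, n: int, p) -> str:
    if n <= 0:
        return ""
    idx = rng.choice(4, size=n, p=list(p))
    return _BASES[idx].tobytes().decode()


def _gc_probs(gc: float):
    return ((1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2)  # A C G T


def _at_probs(at: float):
    return (at / 2, (1 - at) / 2, (1 - at) / 2, at / 2)


# ---------------------------------------------------------------------------
# gene construction

def _lay_gene(utr5: str, cds: str, utr3: str, introns: list[tuple[int, str]]):
    """Insert introns into a transcript; return the genomic (sense) sequence
    and exon/CDS/UTR intervals in gene-local 1-based closed coordinates.

    ``introns`` is a list of (c, sequence): the intron sits after the first
    c transcript bases.
    """
    tx = utr5 + cds + utr3
    L = len(tx)
    cuts = sorted(introns)
    bounds = [0] + [c for c, _ in cuts] + [L]
    parts, exons = [], []
    off = 0
    for i, (s, e) in enumerate(zip(bounds, bounds[1:])):
        exons.append(Interval(s + off + 1, e + off))
        parts.append(tx[s:e])
        if i < len(cuts):
            parts.append(cuts[i][1])
            off += len(cuts[i][1])

    def map_tx(a: int, b: int) -> list[Interval]:
        out, off2 = [], 0
        for i, (s, e) in enumerate(zip(bounds, bounds[1:])):
            lo, hi = max(a, s + 1), min(b, e)
            if hi >= lo:
                out.append(Interval(lo + off2, hi + off2))
            if i < len(cuts):
                off2 += len(cuts[i][1])
        return out

    u5 = map_tx(1, len(utr5)) if utr5 else []
    cds_iv = map_tx(len(utr5) + 1, len(utr5) + len(cds))
    u3 = map_tx(len(utr5) + len(cds) + 1, L) if utr3 else []
    return "".join(parts), exons, cds_iv, u5, u3


def _flip(ivs: list[Interval], glen: int) -> list[Interval]:
    return sorted(Interval(glen - iv.end + 1, glen - iv.start + 1) for iv in ivs)


@dataclass
class _Gene:
    tag: str
    strand: str
    gseq: str
    exons: list[Interval]
    cds: list[Interval]
    utr5: list[Interval]
    utr3: list[Interval]
    truth: dict


def _make_gene(rng: np.random.Generator, spec: SynthesisSpec, tag: str,
               plant_polya: bool) -> _Gene:
    n_codons = int(rng.integers(100, 400))
    cds = "ATG" + "".join(
        _CODONS[i] for i in rng.integers(0, len(_CODONS), size=n_codons)
    ) + "TAA"
    u5_len = max(5, min(300, int(rng.exponential(spec.utr5_mean_len))))
    u3_len = max(12, min(1200, int(rng.exponential(spec.utr3_mean_len))))
    utr5 = _rand_seq(rng, u5_len, _at_probs(spec.utr5_at))
    polya_offset = None
    if plant_polya:
        u3_len = max(u3_len, 46)
        utr3 = list(_rand_seq(rng, u3_len, _gc_probs(spec.utr3_gc)))
        lo, hi = spec.polya_offset_range
        offset = int(rng.integers(lo, hi + 1))
        start = u3_len - offset
        motif = spec.polya_motif.upper().replace("U", "T")
        utr3[start:start + len(motif)] = list(motif)
        if spec.u_rich_flank:
            for i in itertools.chain(
                range(start - 10, start),
                range(start + len(motif), start + len(motif) + 10),
            ):
                if 0 <= i < u3_len:
                    if rng.random() < 0.6:
                        utr3[i] = "T"
                    else:
                        utr3[i] = "ACG"[int(rng.integers(3))]
        utr3 = "".join(utr3)
        polya_offset = -offset
    else:
        utr3 = _rand_seq(rng, u3_len, _gc_probs(spec.utr3_gc))

    n_introns = int(rng.poisson(spec.intron_rate))
    tx_len = len(utr5) + len(cds) + len(utr3)
    cuts: list[tuple[int, str]] = []
    used: set[int] = set()
    in_u5 = in_u3 = 0
    for _ in range(n_introns):
        r = rng.random()
        if r < 0.10 and u5_len >= 30:
            c_lo, c_hi, kind = 2, u5_len - 1, "u5"
        elif r < 0.16 and u3_len >= 60:
            c_lo, c_hi, kind = (
                len(utr5) + len(cds) + 2, tx_len - 2, "u3"
            )
        else:
            c_lo, c_hi, kind = len(utr5) + 4, len(utr5) + len(cds) - 4, "cds"
        for _try in range(10):
            c = int(rng.integers(c_lo, c_hi + 1))
            if c not in used:
                used.add(c)
                ilen = max(40, int(rng.normal(119, 30)))
                cuts.append((c, "GT" + _rand_seq(
                    rng, ilen - 4, _gc_probs(spec.intron_gc)) + "AG"))
                if kind == "u5":
                    in_u5 += 1
                elif kind == "u3":
                    in_u3 += 1
                break
    gseq, exons, cds_iv, u5_iv, u3_iv = _lay_gene(utr5, cds, utr3, cuts)
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        glen = len(gseq)
        gseq = revcomp(gseq)
        exons = _flip(exons, glen)
        cds_iv = _flip(cds_iv, glen)
        u5_iv = _flip(u5_iv, glen)
        u3_iv = _flip(u3_iv, glen)
    protein = translate(SequenceRecord(tag, cds)).seq
    truth = {
        "strand": strand,
        "cds_nt": cds,
        "protein": protein,
        "n_introns": len(cuts),
        "introns_in_utr5": in_u5,
        "introns_in_utr3": in_u3,
        "intron_lengths": sorted(len(s) for _, s in cuts),
        "utr5_len": len(utr5),
        "utr3_len": len(utr3),
        "utr5_seq": utr5,
        "utr3_seq": utr3,
        "polya_offset": polya_offset,
    }
    return _Gene(tag, strand, gseq, exons, cds_iv, u5_iv, u3_iv, truth)


def _shift(ivs: Sequence[Interval], off: int) -> list[Interval]:
    return [Interval(iv.start + off, iv.end + off) for iv in ivs]


def make_genome(spec: SynthesisSpec):
    """Generate (contigs, gene models, manifest) for the truth assembly."""
    spec.validate()
    rng = _rng(spec.seed, 1)
    contigs: list[SequenceRecord] = []
    models: list[GeneModel] = []
    manifest: dict = {
        "contigs": {}, "genes": {}, "full_length_genes": [],
    }
    per_contig = [spec.n_genes // spec.n_contigs] * spec.n_contigs
    for i in range(spec.n_genes % spec.n_contigs):
        per_contig[i] += 1
    telo = spec.telomere_unit.upper() * spec.telomere_units_per_end
    gene_no = 1
    for ci in range(spec.n_contigs):
        cid = f"contig_{ci + 1:02d}"
        telo5 = telo3 = False
        if ci < spec.n_both_telomeres:
            telo5 = telo3 = True
        elif ci < spec.n_both_telomeres + spec.n_one_telomere:
            if rng.random() < 0.5:
                telo5 = True
            else:
                telo3 = True
        parts: list[str] = []
        pos = 0
        if telo5:
            parts.append(telo)
            pos += len(telo)
        lead = int(rng.integers(300, 800))
        parts.append(_rand_seq(rng, lead, _gc_probs(spec.gc_background)))
        pos += lead
        for _ in range(per_contig[ci]):
            tag = f"{spec.locus_prefix}{gene_no}"
            gene_no += 1
            plant = rng.random() < spec.polya_plant_fraction
            g = _make_gene(rng, spec, tag, plant)
            parts.append(g.gseq)
            model = GeneModel(
                locus_tag=tag, contig_id=cid, strand=g.strand,
                exons=_shift(g.exons, pos), cds=_shift(g.cds, pos),
                utr5=_shift(g.utr5, pos), utr3=_shift(g.utr3, pos),
            )
            model.validate()
            models.append(model)
            pos += len(g.gseq)
            gap = min(4000, int(rng.exponential(spec.mean_intergenic - 200)) + 200)
            parts.append(_rand_seq(rng, gap, _gc_probs(spec.gc_background)))
            pos += gap
            truth = dict(g.truth)
            truth["contig"] = cid
            truth["span"] = [model.span.start, model.span.end]
            full = bool(truth["utr3_len"] and rng.random()
                        < spec.full_length_fraction)
            truth["full_length"] = full
            if full:
                manifest["full_length_genes"].append(tag)
            manifest["genes"][tag] = truth
        if telo3:
            parts.append(revcomp(telo))
            pos += len(telo)
        seq = "".join(parts)
        if spec.max_contig_len is not None and len(seq) > spec.max_contig_len:
            raise SizingError(
                f"{cid}: generated length {len(seq)} exceeds "
                f"max_contig_len={spec.max_contig_len}"
            )
        contigs.append(SequenceRecord(cid, seq))
        manifest["contigs"][cid] = {
            "telo5": telo5, "telo3": telo3, "length": len(seq),
        }
    manifest["assembly"] = {
        "n_both": spec.n_both_telomeres,
        "n_one": spec.n_one_telomere,
    }
    manifest["metrics"] = _truth_metrics(models, manifest)
    return contigs, models, manifest


def _truth_metrics(models: Sequence[GeneModel], manifest) -> dict:
    genes = manifest["genes"]
    n = len(models)
    return {
        "n_genes": n,
        "mean_gene_length": float(np.mean([len(m.span) for m in models])),
        "n_introns": int(sum(g["n_introns"] for g in genes.values())),
        "n_introns_in_utr5": int(
            sum(g["introns_in_utr5"] for g in genes.values())),
        "n_introns_in_utr3": int(
            sum(g["introns_in_utr3"] for g in genes.values())),
        "n_genes_with_utr5": int(sum(1 for g in genes.values() if g["utr5_len"])),
        "n_genes_with_utr3": int(sum(1 for g in genes.values() if g["utr3_len"])),
        "mean_utr5_length": float(np.mean(
            [g["utr5_len"] for g in genes.values() if g["utr5_len"]] or [0])),
        "mean_utr3_length": float(np.mean(
            [g["utr3_len"] for g in genes.values() if g["utr3_len"]] or [0])),
    }


# ---------------------------------------------------------------------------
# old-assembly derivation

@dataclass
class OldAssembly:
    contigs: list[SequenceRecord]
    models: list[GeneModel]
    mapped_models: list[GeneModel]   # old models lifted onto new coordinates
    categories: dict[str, str]
    correspondence: dict[str, dict]


def _clip(ivs: Sequence[Interval], lo: int, hi: int) -> list[Interval]:
    out = []
    for iv in ivs:
        s, e = max(iv.start, lo), min(iv.end, hi)
        if e >= s:
            out.append(Interval(s, e))
    return out


def derive_old_assembly(
    contigs: Sequence[SequenceRecord],
    models: Sequence[GeneModel],
    spec: SynthesisSpec,
) -> OldAssembly:
    """Derive a fragmented "old" assembly with planted transfer events.

    Event names follow the old->new transfer direction: a *fusion* event
    plants two old models that the transfer fuses into one new model (the
    new gene is represented as two partial old models); a *split* event
    plants one old model — two adjacent genes merged by a fake long intron —
    that the transfer splits in two; a *frameshift* event plants a
    compensated 1-bp insertion/deletion pair inside one CDS exon, so the old
    CDS keeps its length but only matches at near identity.  Contaminant
    genes live on an old-only contig and can never transfer.
    """
    spec.validate()
    rng = _rng(spec.seed, 2)
    by_contig: dict[str, list[GeneModel]] = {}
    for m in models:
        by_contig.setdefault(m.contig_id, []).append(m)
    for ms in by_contig.values():
        ms.sort(key=lambda m: m.span.start)
    used: set[str] = set()

    # split events: adjacent plus-strand pairs merged into one old model
    split_pairs: list[tuple[GeneModel, GeneModel]] = []
    for ms in by_contig.values():
        for a, b in zip(ms, ms[1:]):
            if len(split_pairs) == spec.n_split_events:
                break
            if (a.strand == b.strand == "+"
                    and a.locus_tag not in used and b.locus_tag not in used):
                split_pairs.append((a, b))
                used.update((a.locus_tag, b.locus_tag))
    if len(split_pairs) < spec.n_split_events:
        raise SizingError("not enough adjacent plus-strand pairs for splits")

    def pick(pred, n, what):
        chosen = []
        for m in models:
            if len(chosen) == n:
                break
            if m.locus_tag not in used and pred(m):
                chosen.append(m)
                used.add(m.locus_tag)
        if len(chosen) < n:
            raise SizingError(f"not enough genes for {what} events")
        return chosen

    fusion_genes = pick(
        lambda m: m.strand == "+" and m.cds_length >= 300,
        spec.n_fusion_events, "fusion")
    frameshift_genes = pick(
        lambda m: m.strand == "+" and m.cds_length >= 720
        and any(len(iv) >= 120 for iv in m.cds),
        spec.n_frameshift_events, "frameshift")

    prefix = spec.locus_prefix
    fresh = itertools.count(spec.n_genes + 1001)
    mapped: list[GeneModel] = []
    correspondence: dict[str, dict] = {}
    categories: dict[str, str] = {}
    from .annotation_transfer import fusion_name, split_names

    for m in models:
        tag = m.locus_tag
        if tag in used:
            continue
        mapped.append(dataclasses.replace(m))
        correspondence[tag] = {
            "outcome": "transferred", "stage": "denovo_evm", "new_tags": [tag],
        }

    for g in fusion_genes:
        half = 3 * (g.cds_length // 6)
        acc = 0
        cut = None
        for iv in g.cds:
            if acc + len(iv) >= half:
                cut = iv.start + (half - acc) - 1
                break
            acc += len(iv)
        a_tag, b_tag = g.locus_tag, f"{prefix}{next(fresh)}"
        left = GeneModel(
            a_tag, g.contig_id, "+",
            exons=_clip(g.exons, 1, cut), cds=_clip(g.cds, 1, cut),
            utr5=_clip(g.utr5, 1, cut),
        )
        right = GeneModel(
            b_tag, g.contig_id, "+",
            exons=_clip(g.exons, cut + 1, 10 ** 9),
            cds=_clip(g.cds, cut + 1, 10 ** 9),
            utr3=_clip(g.utr3, cut + 1, 10 ** 9),
        )
        mapped.extend((left, right))
        name = fusion_name([a_tag, b_tag])
        for t in (a_tag, b_tag):
            correspondence[t] = {
                "outcome": "fused", "stage": "manual", "new_tags": [name],
            }

    for a, b in split_pairs:
        tag = a.locus_tag
        merged = GeneModel(
            tag, a.contig_id, "+",
            exons=sorted(a.exons + b.exons),
            cds=sorted(a.cds + b.cds),
            utr5=list(a.utr5), utr3=list(b.utr3),
        )
        mapped.append(merged)
        correspondence[tag] = {
            "outcome": "split", "stage": "manual",
            "new_tags": split_names(tag, 2),
            "new_models": [a.locus_tag, b.locus_tag],
        }

    for g in frameshift_genes:
        mapped.append(dataclasses.replace(g))
        correspondence[g.locus_tag] = {
            "outcome": "transferred", "stage": "gmap",
            "new_tags": [g.locus_tag],
        }

    # fragment each contig between genes (never inside a merged split pair)
    merged_right = {b.locus_tag for _, b in split_pairs}
    old_contigs: list[SequenceRecord] = []
    old_models: list[GeneModel] = []
    mapped_by_contig: dict[str, list[GeneModel]] = {}
    for m in mapped:
        mapped_by_contig.setdefault(m.contig_id, []).append(m)
    fs_tags = {g.locus_tag for g in frameshift_genes}
    for contig in contigs:
        ms = sorted(mapped_by_contig.get(contig.id, []),
                    key=lambda m: m.span.start)
        cut_candidates = [
            (a.span.end + b.span.start) // 2
            for a, b in zip(ms, ms[1:])
            if b.span.start > a.span.end + 1
            and b.locus_tag not in merged_right
        ]
        n_cuts = min(len(cut_candidates), int(rng.integers(1, 3)))
        cuts = sorted(
            rng.choice(len(cut_candidates), size=n_cuts, replace=False)
        ) if n_cuts else []
        bounds = [0] + [cut_candidates[i] for i in cuts] + [len(contig.seq)]
        for fi, (s, e) in enumerate(zip(bounds, bounds[1:])):
            oid = f"old_{contig.id}_{fi + 1}"
            frag = list(contig.seq[s:e])
            frag_models = [
                m for m in ms if s + 1 <= m.span.start and m.span.end <= e
            ]
            for m in frag_models:
                om = GeneModel(
                    m.locus_tag, oid, m.strand,
                    exons=_shift(m.exons, -s), cds=_shift(m.cds, -s),
                    utr5=_shift(m.utr5, -s), utr3=_shift(m.utr3, -s),
                )
                if m.locus_tag in fs_tags:
                    big = max(om.cds, key=len)
                    q = big.start - 1 + 20           # 0-based in fragment
                    ins = "ACGT"[int(rng.integers(4))]
                    frag[q:q] = [ins]
                    del frag[q + 31]
                old_models.append(om)
            old_contigs.append(SequenceRecord(oid, "".join(frag)))

    if spec.n_contaminant_genes:
        crng = rng
        parts, pos = [], 0
        lead = int(crng.integers(200, 500))
        parts.append(_rand_seq(crng, lead, _gc_probs(0.5)))
        pos += lead
        for _ in range(spec.n_contaminant_genes):
            tag = f"{prefix}{next(fresh)}"
            g = _make_gene(crng, spec, tag, plant_polya=False)
            parts.append(g.gseq)
            old_models.append(GeneModel(
                tag, "old_contaminant_1", g.strand,
                exons=_shift(g.exons, pos), cds=_shift(g.cds, pos),
                utr5=_shift(g.utr5, pos), utr3=_shift(g.utr3, pos),
            ))
            pos += len(g.gseq)
            gap = int(crng.integers(300, 900))
            parts.append(_rand_seq(crng, gap, _gc_probs(0.5)))
            pos += gap
            categories[tag] = "contaminant"
            correspondence[tag] = {
                "outcome": "contaminant", "stage": None, "new_tags": [],
            }
        old_contigs.append(SequenceRecord("old_contaminant_1", "".join(parts)))

    old_models.sort(key=lambda m: (m.contig_id, m.span.start))
    return OldAssembly(old_contigs, old_models, mapped, categories,
                       correspondence)


# ---------------------------------------------------------------------------
# transcript evidence

def make_transcript_evidence(
    models: Sequence[GeneModel], spec: SynthesisSpec, manifest: Mapping,
) -> pd.DataFrame:
    """Per-read alignment records with polyA/oligo-dT boundary positions.

    Genes flagged full-length in the manifest get at least one read that
    covers the whole gene span with its boundary exactly at the annotated
    3'UTR end.  Other genes with a 3'UTR get either no reads, a read that
    does not cover the UTR, or a read whose boundary falls short.
    """
    rng = _rng(spec.seed, 3)
    rows = []
    rid = itertools.count(1)
    full = set(manifest["full_length_genes"])
    for m in models:
        if not m.utr3:
            continue
        span = m.span
        utr_lo = m.utr3[0].start
        utr_hi = m.utr3[-1].end
        end_coord = utr_hi if m.strand == "+" else utr_lo
        if m.locus_tag in full:
            n_reads = int(rng.integers(1, 4))
            for k in range(n_reads):
                if k == 0:
                    a, b = span.start, span.end
                    boundary = end_coord
                else:  # extra 5'-truncated read, still ending at the site
                    trunc = int(rng.integers(10, max(11, len(span) // 2)))
                    if m.strand == "+":
                        a, b = span.start + trunc, span.end
                    else:
                        a, b = span.start, span.end - trunc
                    boundary = end_coord
                rows.append((f"read_{next(rid):06d}", m.locus_tag,
                             m.contig_id, a, b, boundary))
        else:
            mode = rng.random()
            if mode < 0.25:
                continue  # no reads at all
            if mode < 0.625:  # alignment does not cover the UTR
                inset = int(rng.integers(5, 40))
                if m.strand == "+":
                    a = min(utr_lo + inset, utr_hi)
                    b = span.end
                    boundary = end_coord
                else:
                    a = span.start
                    b = max(utr_hi - inset, utr_lo)
                    boundary = end_coord
            else:  # boundary falls short of the annotated end
                short = int(rng.integers(6, 40))
                a, b = span.start, span.end
                boundary = (end_coord - short if m.strand == "+"
                            else end_coord + short)
            rows.append((f"read_{next(rid):06d}", m.locus_tag,
                         m.contig_id, a, b, boundary))
    return pd.DataFrame(rows, columns=READ_COLUMNS)


# ---------------------------------------------------------------------------
# proteome

@dataclass
class Proteome:
    proteins: list[SequenceRecord]
    ss3: list[SequenceRecord]
    scores: pd.DataFrame
    tmd: pd.DataFrame
    hits_fwd: list[HitRecord]
    hits_rev: list[HitRecord]
    hmm_hits: pd.DataFrame
    db_hits: pd.DataFrame
    manifest: dict


def _rand_protein(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, 20, size=n)
    return "".join(_AA20[i] for i in idx)


def _rand_ss3(rng: np.random.Generator, n: int) -> str:
    idx = rng.choice(3, size=n, p=[0.30, 0.20, 0.50])
    return "".join("HEC"[i] for i in idx)


def _beta_signal(rng: np.random.Generator) -> str:
    pick = lambda s: s[int(rng.integers(len(s)))]
    return "".join([
        pick(POLAR), pick(_AA20), "G", pick(HYDROPHOBIC), pick(_AA20),
        pick(HYDROPHOBIC), pick(_AA20), pick(HYDROPHOBIC),
    ])


def _structured_ss(rng, n, e_frac, h_frac) -> str:
    ne, nh = int(round(e_frac * n)), int(round(h_frac * n))
    arr = ["E"] * ne + ["H"] * nh + ["C"] * (n - ne - nh)
    perm = rng.permutation(n)
    return "".join(arr[i] for i in perm)


def _hit(q, s, evalue, rng) -> HitRecord:
    aln = int(rng.integers(80, 400))
    pid = float(rng.uniform(30, 95))
    bits = max(25.0, 60.0 - 2.0 * np.log10(evalue))
    return HitRecord(q, s, round(pid, 2), aln,
                     int(aln * (100 - pid) / 100), int(rng.integers(0, 4)),
                     1, aln, 1, aln, float(evalue), round(bits, 1))


def make_proteome(spec: SynthesisSpec) -> Proteome:
    """Proteome with planted mito-screen positives, decoys and RBH pairs.

    Targeting positives score Uniform(0.55, 0.95) on both predictors, all
    other proteins at most 0.45 on at least one; tail-anchor positives carry
    a 20-aa hydrophobic stretch ending within 32 aa of the C-terminus (with
    a matching TMD-table row), TA decoys one ending 33-60 aa away; MBOMP
    positives end in a Po-x-G-Hy-x-Hy-x-Hy 8-mer with a strand-rich,
    helix-poor 300-aa context, and each MBOMP decoy violates exactly one of
    the three secondary-structure filters.  Homology tables contain the
    planted mutual-best pairs at e <= 0.001 plus non-reciprocal noise hits
    with e-values log-uniform in [1e-3, 10].
    """
    spec.validate()
    rng = _rng(spec.seed, 4)
    n = spec.n_proteins
    roles_needed = (
        spec.n_targeting_pos + spec.n_targeting_decoy + spec.n_ta_pos
        + spec.n_ta_decoy + spec.n_mbomp_pos + spec.n_mbomp_decoy
        + spec.n_rbh_pairs + spec.n_hmm_hits + spec.n_noise_hits
    )
    if roles_needed > n:
        raise SizingError(
            f"{roles_needed} planted roles exceed proteome size {n}"
        )
    ids = [f"P{i + 1:05d}" for i in range(n)]
    order = rng.permutation(n)
    it = iter(order)

    def take(k):
        return sorted(ids[next(it)] for _ in range(k))

    targeting = take(spec.n_targeting_pos)
    targeting_decoy = take(spec.n_targeting_decoy)
    ta = take(spec.n_ta_pos)
    ta_decoy = take(spec.n_ta_decoy)
    mbomp = take(spec.n_mbomp_pos)
    mbomp_decoy = take(spec.n_mbomp_decoy)
    rbh_prots = take(spec.n_rbh_pairs)
    hmm_prots = take(spec.n_hmm_hits)
    noise_prots = take(spec.n_noise_hits)

    from .io_core import PipelineConfig as _PC
    _cfg = _PC()
    min_len = _cfg.mbomp_context + _cfg.beta_signal_len
    seqs: dict[str, str] = {}
    ss: dict[str, str] = {}
    tmd_rows = []
    mbomp_all = set(mbomp) | set(mbomp_decoy)
    for pid in ids:
        ln = int(rng.integers(120, 600))
        if pid in mbomp_all:
            ln = min_len + int(rng.integers(0, 8))
        seq = _rand_protein(rng, ln)
        sstr = _rand_ss3(rng, ln)
        if pid in set(ta) | set(ta_decoy):
            dist = (int(rng.integers(0, 13)) if pid in set(ta)
                    else int(rng.integers(33, 61)))
            end = ln - dist
            start = end - 19
            stretch = "".join(
                "LIVF"[int(rng.integers(4))] for _ in range(20))
            seq = seq[:start - 1] + stretch + seq[end:]
            tmd_rows.append((pid, start, end, "external_table"))
        if pid in mbomp_all:
            motif = _beta_signal(rng)
            # proline spacer: P is neither polar nor hydrophobic here, so the
            # planted 8-mer is the only beta-signal in the C-terminal window
            seq = seq[:ln - 23] + "P" * 15 + motif
            ctx = _cfg.mbomp_context
            if pid in set(mbomp):
                ctx_ss = _structured_ss(rng, ctx, 0.35, 0.05)
                motif_ss = "CECCECCE"
            else:
                kind = mbomp_decoy.index(pid) % 3
                if kind == 0:    # too little strand
                    ctx_ss = _structured_ss(rng, ctx, 0.15, 0.05)
                    motif_ss = "CECCECCE"
                elif kind == 1:  # too much helix
                    ctx_ss = _structured_ss(rng, ctx, 0.35, 0.20)
                    motif_ss = "CECCECCE"
                else:            # helical beta-signal
                    ctx_ss = _structured_ss(rng, ctx, 0.35, 0.05)
                    motif_ss = "HHHHHCCC"
            head = sstr[:ln - 8 - ctx]
            sstr = head + ctx_ss + motif_ss
        seqs[pid] = seq
        ss[pid] = sstr

    score_rows = []
    for pid in ids:
        if pid in set(targeting):
            pa = float(rng.uniform(0.55, 0.95))
            pb = float(rng.uniform(0.55, 0.95))
        elif pid in set(targeting_decoy):
            hi, lo = float(rng.uniform(0.55, 0.95)), float(rng.uniform(0, 0.45))
            pa, pb = (hi, lo) if rng.random() < 0.5 else (lo, hi)
        else:
            pa = float(rng.uniform(0, 0.45))
            pb = float(rng.uniform(0, 0.45))
        score_rows.append((pid, "targetp", round(pa, 4)))
        score_rows.append((pid, "mitofates", round(pb, 4)))

    fwd, rev = [], []
    rbh_pairs = []
    for i, pid in enumerate(rbh_prots):
        subj = f"MMDB_{i + 1:04d}"
        e = 10.0 ** rng.uniform(-30, -4)
        fwd.append(_hit(pid, subj, e, rng))
        rev.append(_hit(subj, pid, 10.0 ** rng.uniform(-30, -4), rng))
        rbh_pairs.append((pid, subj))
        if rng.random() < 0.4:  # extra, worse hit for the same query
            fwd.append(_hit(pid, f"NOISE_{i:04d}",
                            10.0 ** rng.uniform(-3, 1), rng))
    m = len(noise_prots)
    for i, pid in enumerate(noise_prots):
        subj = f"NOISE_{1000 + i:04d}"
        fwd.append(_hit(pid, subj, 10.0 ** rng.uniform(-3, 1), rng))
        rev.append(_hit(subj, noise_prots[(i + 1) % m],
                        10.0 ** rng.uniform(-3, 1), rng))

    hmm_rows = [
        (pid, f"PF{int(rng.integers(1, 20000)):05d}",
         10.0 ** rng.uniform(-20, -5))
        for pid in hmm_prots
    ]
    with_homolog = hmm_prots[:spec.n_hmm_with_homolog]
    db_rows = [
        (pid, f"MMDB_{int(rng.integers(5000, 6979)):04d}",
         10.0 ** rng.uniform(-20, -4))
        for pid in with_homolog
    ]

    manifest = {
        "targeting": targeting, "targeting_decoys": targeting_decoy,
        "ta": ta, "ta_decoys": ta_decoy,
        "mbomp": mbomp, "mbomp_decoys": mbomp_decoy,
        "rbh_pairs": [list(p) for p in rbh_pairs],
        "hmm": hmm_prots, "hmm_with_homolog": with_homolog,
        "n_proteins": n,
    }
    return Proteome(
        proteins=[SequenceRecord(p, seqs[p], alphabet="protein") for p in ids],
        ss3=[SequenceRecord(p, ss[p], alphabet="ss3") for p in ids],
        scores=pd.DataFrame(score_rows, columns=SCORE_COLUMNS),
        tmd=pd.DataFrame(tmd_rows, columns=TMD_COLUMNS),
        hits_fwd=fwd, hits_rev=rev,
        hmm_hits=pd.DataFrame(hmm_rows, columns=HMM_COLUMNS),
        db_hits=pd.DataFrame(db_rows, columns=DB_COLUMNS),
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# corpus assembly and serialisation

@dataclass
class Corpus:
    spec: SynthesisSpec
    contigs: list[SequenceRecord]
    models: list[GeneModel]
    old: OldAssembly
    reads: pd.DataFrame
    proteome: Proteome
    manifest: dict

    def old_cds(self) -> dict[str, str]:
        return cds_sequences(self.old.contigs, self.old.models)

    def new_cds(self) -> dict[str, str]:
        return cds_sequences(self.contigs, self.models)

    def stage_candidates(self) -> dict[str, dict[str, str]]:
        cds = self.new_cds()
        return {"denovo_evm": cds, "gmap": cds}


def generate_corpus(spec: SynthesisSpec) -> Corpus:
    contigs, models, manifest = make_genome(spec)
    old = derive_old_assembly(contigs, models, spec)
    reads = make_transcript_evidence(models, spec, manifest)
    proteome = make_proteome(spec)
    manifest["correspondence"] = old.correspondence
    manifest["events"] = {
        "fusion": spec.n_fusion_events,
        "split": spec.n_split_events,
        "frameshift": spec.n_frameshift_events,
        "contaminant": spec.n_contaminant_genes,
    }
    manifest["proteome"] = proteome.manifest
    manifest["spec"] = dataclasses.asdict(spec)
    return Corpus(spec, contigs, models, old, reads, proteome, manifest)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_tsv(path, columns: Sequence[str]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", names=list(columns))


def write_corpus(corpus: Corpus, outdir) -> None:
    """Write every corpus artifact (FASTA/GFF3/TSV/JSON) into a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(corpus.contigs, out / "genome.fasta")
    write_gff3(corpus.models, out / "annotation.gff3")
    write_fasta(corpus.old.contigs, out / "old_assembly.fasta")
    write_gff3(corpus.old.models, out / "old_annotation.gff3")
    write_gff3(corpus.old.mapped_models, out / "old_mapped.gff3")
    _write_tsv(corpus.reads, out / "reads.tsv")
    write_fasta(corpus.proteome.proteins, out / "proteome.faa")
    write_fasta(corpus.proteome.ss3, out / "ss3.faa")
    _write_tsv(corpus.proteome.scores, out / "targeting_scores.tsv")
    _write_tsv(corpus.proteome.tmd, out / "tmd.tsv")
    _write_tsv(corpus.proteome.hmm_hits, out / "hmm_hits.tsv")
    _write_tsv(corpus.proteome.db_hits, out / "db_hits.tsv")
    write_hits(corpus.proteome.hits_fwd, out / "hits_fwd.tsv")
    write_hits(corpus.proteome.hits_rev, out / "hits_rev.tsv")
    (out / "truth.json").write_text(
        json.dumps(corpus.manifest, sort_keys=True, indent=1) + "\n"
    )
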