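"""Batch orchestration: submission parsing, per-design runs, CSV/GenBank output.

A submission is a CSV with one design request per row. The ``target`` column
accepts three forms: ``TRANSCRIPT,N`` / ``TRANSCRIPT,C`` (in-frame payload
immediately after the start codon or before the stop codon), ``chrom:pos``
(1-based; payload inserted immediately after that base), or
``TRANSCRIPT,chrom:pos`` (coordinate target with transcript context for the
positional guide weight and splice protection). Every other column is
optional and falls back to documented defaults; different rows may use
different parameters.

Runs are deterministic and per-design isolated: one failing row never
aborts the batch.
"""

from __future__ import annotations

import csv
import logging
import time
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .cfd import CFDModel
from .donor import DonorDesign, DonorSpec, build_donor
from .enzymes import get_enzyme
from .genome import GenomeIndex, TranscriptModel, resolve_transcript
from .genoprimer import PrimerPairReport, design_genotyping_primers
from .guides import GuideCandidate, design_guides
from .recoding import CodonUsageTable
from .sequences import revcomp

log = logging.getLogger(__name__)

DEFAULTS = dict(
    enzyme="SpCas9",
    num_guides=1,
    donor_mode="dsDNA",
    arm5_len=500,
    arm3_len=500,
    ssodn_max_len=200,
    recoding_level="full",
    strand_mode="auto",
    trim_enabled=False,
    min_arm_len=100,
    forbidden_motifs="",
    cfd_threshold=0.03,
    recut_priority="PAM_first",
    coding_only=False,
    position_weight=True,
    primer_mode="",
    max_mismatches=4,
    search_radius=50,
)

_BOOL = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False, "": False}


@dataclass
class DesignRequest:
    design_id: str
    transcript_id: str | None = None
    terminus: str | None = None          # "N" | "C"
    chrom: str | None = None
    position: int | None = None          # 1-based
    payload: str = ""
    enzyme: str = "SpCas9"
    num_guides: int = 1
    donor_mode: str = "dsDNA"
    arm5_len: int = 500
    arm3_len: int = 500
    ssodn_max_len: int = 200
    recoding_level: str = "full"
    strand_mode: str = "auto"
    trim_enabled: bool = False
    min_arm_len: int = 100
    forbidden_motifs: str = ""
    cfd_threshold: float = 0.03
    recut_priority: str = "PAM_first"
    coding_only: bool = False
    position_weight: bool = True
    primer_mode: str = ""                # "" | "short" | "long"
    max_mismatches: int = 4
    search_radius: int = 50
    parse_error: str | None = None

    @property
    def target_string(self) -> str:
        if self.transcript_id and self.terminus:
            return f"{self.transcript_id},{self.terminus}"
        coord = f"{self.chrom}:{self.position}" if self.chrom else ""
        if self.transcript_id:
            return f"{self.transcript_id},{coord}"
        return coord

    def donor_spec(self) -> DonorSpec:
        motifs = tuple(m for m in self.forbidden_motifs.split("|") if m)
        return DonorSpec(
            mode=self.donor_mode, arm5_len=self.arm5_len, arm3_len=self.arm3_len,
            ssodn_max_len=self.ssodn_max_len, recoding_level=self.recoding_level,
            strand_mode=self.strand_mode, trim_enabled=self.trim_enabled,
            min_arm_len=self.min_arm_len, forbidden_motifs=motifs,
            cfd_threshold=self.cfd_threshold, recut_priority=self.recut_priority,
            coding_only=self.coding_only,
        )


@dataclass
class DesignResult:
    request: DesignRequest
    guides: list[GuideCandidate] = field(default_factory=list)
    donor: DonorDesign | None = None
    primers: list[PrimerPairReport] = field(default_factory=list)
    primer_failure: str | None = None
    error: str | None = None
    warnings: list[str] = field(default_factory=list)
    elapsed: float = 0.0


def _parse_target(req: DesignRequest, text: str) -> None:
    text = text.strip()
    parts = [p.strip() for p in text.split(",")]
    def set_coord(tok):
        chrom, _, pos = tok.partition(":")
        if not chrom or not pos or not pos.isdigit():
            raise ValueError(f"malformed coordinate {tok!r}")
        req.chrom, req.position = chrom, int(pos)
    if len(parts) == 1:
        if ":" in parts[0]:
            set_coord(parts[0])
        else:
            raise ValueError(f"malformed target {text!r}")
    elif len(parts) == 2:
        if parts[1] in ("N", "C"):
            req.transcript_id, req.terminus = parts[0], parts[1]
        elif ":" in parts[1]:
            req.transcript_id = parts[0]
            set_coord(parts[1])
        else:
            raise ValueError(f"malformed target {text!r}")
    else:
        raise ValueError(f"malformed target {text!r}")


def parse_submission(source, config: dict | None = None) -> list[DesignRequest]:
    """Parse a submission CSV (path or iterable of dict rows).

    Malformed rows yield a request with ``parse_error`` set so the batch can
    proceed and report the failure per design.
    """
    if isinstance(source, (str, Path)):
        with open(source, newline="") as fh:
            rows = list(csv.DictReader(fh))
    else:
        rows = [dict(r) for r in source]
    base = dict(DEFAULTS)
    base.update(config or {})
    requests = []
    for i, row in enumerate(rows):
        row = {k.strip(): (v or "").strip() if isinstance(v, str) else v
               for k, v in row.items() if k}
        req = DesignRequest(design_id=row.get("design_id") or f"design_{i + 1}")
        try:
            merged = {**base, **{k: v for k, v in row.items() if v not in ("", None)}}
            req.payload = str(merged.get("payload", "")).upper()
            for f in fields(DesignRequest):
                if f.name in ("design_id", "payload", "transcript_id", "terminus",
                              "chrom", "position", "parse_error"):
                    continue
                if f.name in merged:
                    v = merged[f.name]
                    if f.type == "bool" or isinstance(getattr(req, f.name), bool):
                        v = _BOOL[str(v).lower()] if isinstance(v, str) else bool(v)
                    elif isinstance(getattr(req, f.name), int):
                        v = int(v)
                    elif isinstance(getattr(req, f.name), float):
                        v = float(v)
                    setattr(req, f.name, v)
            target = row.get("target", "")
            if not target:
                raise ValueError("missing target")
            _parse_target(req, target)
            get_enzyme(req.enzyme)
        except Exception as exc:  # row-level isolation
            req.parse_error = str(exc)
        requests.append(req)
    return requests


def _resolve_site(
    req: DesignRequest, models: dict[str, TranscriptModel], genome: GenomeIndex
) -> tuple[str, int, TranscriptModel | None, str]:
    """(chrom, insertion gap coordinate, transcript context, oriented payload)."""
    model = None
    if req.transcript_id:
        model = resolve_transcript(models, req.transcript_id)
    if req.chrom is not None:
        chrom, gap = req.chrom, req.position  # insert after the 1-based base
        if chrom not in genome.sequences:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not 0 <= gap <= genome.lengths[chrom]:
            raise ValueError(f"position {req.position} outside {chrom}")
        payload = req.payload
        return chrom, gap, model, payload
    gap = model.insertion_gap(req.terminus)
    payload = req.payload if model.strand == "+" else revcomp(req.payload)
    return model.chrom, gap, model, payload


def run_design(
    req: DesignRequest,
    genome: GenomeIndex,
    models: dict[str, TranscriptModel],
    usage: CodonUsageTable | None = None,
) -> DesignResult:
    res = DesignResult(request=req)
    t0 = time.perf_counter()
    try:
        if req.parse_error:
            raise ValueError(req.parse_error)
        enzyme = get_enzyme(req.enzyme)
        chrom, gap, model, payload = _resolve_site(req, models, genome)
        res.guides = design_guides(
            genome, enzyme, chrom, gap, k=req.num_guides,
            search_radius=req.search_radius, model=model,
            position_enabled=req.position_weight, max_mismatches=req.max_mismatches,
        )
        if payload:
            if not res.guides:
                raise ValueError("no guide found in the search window; donor skipped")
            cfd_model = CFDModel.load(enzyme)
            res.donor = build_donor(
                genome, chrom, gap, payload, req.donor_spec(),
                guide=res.guides[0], model=model, cfd_model=cfd_model, usage=usage,
            )
            res.warnings.extend(res.donor.warnings)
        if req.primer_mode:
            res.primers, res.primer_failure = design_genotyping_primers(
                genome, chrom, gap, mode=req.primer_mode,
            )
    except Exception as exc:
        res.error = str(exc)
        log.warning("design %s failed: %s", req.design_id, exc)
    res.elapsed = time.perf_counter() - t0
    return res


def run_designs(
    requests: list[DesignRequest],
    genome: GenomeIndex,
    models: dict[str, TranscriptModel],
    usage: CodonUsageTable | None = None,
) -> list[DesignResult]:
    return [run_design(r, genome, models, usage) for r in requests]


GUIDE_COLS = [
    "design_id", "enzyme", "rank", "protospacer", "PAM", "chrom", "cut_site",
    "strand", "distance_to_insert", "specificity_score",
    "w_spec", "w_dist", "w_pos", "composite",
]
DONOR_COLS = [
    "donor_mode", "donor_strand", "donor_sequence", "donor_length",
    "arm5_len", "arm3_len", "effective_arm5", "effective_arm3",
    "recoding_level", "n_recoding_mutations", "residual_max_cfd",
    "recut_above_threshold", "flag_homopolymer", "flag_gc_global",
    "flag_gc_skew", "flag_forbidden_motifs",
]
PRIMER_COLS = [
    "primer_attempt", "primer_verdict", "fwd_seq", "fwd_tm", "fwd_gc",
    "rev_seq", "rev_tm", "rev_gc", "product_size", "annealing_temp",
    "primer_failure",
]


def _result_rows(res: DesignResult) -> list[dict]:
    rows = []
    req = res.request
    if res.error:
        return [{"design_id": req.design_id, "error": res.error}]
    for rank, g in enumerate(res.guides, start=1):
        row = {
            "design_id": req.design_id, "enzyme": req.enzyme, "rank": rank,
            "protospacer": g.protospacer, "PAM": g.pam, "chrom": g.chrom,
            "cut_site": g.cut_site_1based, "strand": g.strand,
            "distance_to_insert": g.distance_to_insert,
            "specificity_score": round(g.specificity_score, 4),
            "w_spec": round(g.w_spec, 6), "w_dist": round(g.w_dist, 6),
            "w_pos": round(g.w_pos, 6), "composite": round(g.composite, 6),
            "error": "",
        }
        if rank == 1 and res.donor is not None:
            d = res.donor
            eff5, eff3 = d.effective_arm_lens
            row.update({
                "donor_mode": d.mode, "donor_strand": d.strand,
                "donor_sequence": d.sequence, "donor_length": len(d.sequence),
                "arm5_len": d.arm5_len, "arm3_len": d.arm3_len,
                "effective_arm5": eff5, "effective_arm3": eff3,
                "recoding_level": d.plan.level,
                "n_recoding_mutations": len(d.plan.mutations),
                "residual_max_cfd": round(d.plan.residual_max_cfd, 6),
                "recut_above_threshold": d.plan.above_threshold,
                "flag_homopolymer": ";".join(
                    f"{r.base}x{r.length}@{r.offset + 1}" for r in d.flags.homopolymers),
                "flag_gc_global": f"{d.flags.gc_global_pct:.1f}" if d.flags.gc_global_flag else "",
                "flag_gc_skew": f"{d.flags.gc_skew_pct:.1f}" if d.flags.gc_skew_flag else "",
                "flag_forbidden_motifs": ";".join(
                    f"{m}@{o + 1}" for m, o in d.flags.forbidden_motif_hits),
            })
        if rank == 1 and (res.primers or res.primer_failure):
            if res.primers:
                p = res.primers[0]
                row.update({
                    "primer_attempt": p.attempt, "primer_verdict": p.verdict,
                    "fwd_seq": p.fwd.sequence, "fwd_tm": round(p.fwd.tm, 2),
                    "fwd_gc": round(p.fwd.gc, 1),
                    "rev_seq": p.rev.sequence, "rev_tm": round(p.rev.tm, 2),
                    "rev_gc": round(p.rev.gc, 1),
                    "product_size": p.product_size,
                    "annealing_temp": round(p.annealing_temp, 2),
                })
            row["primer_failure"] = res.primer_failure or ""
        rows.append(row)
    if not rows:
        rows = [{"design_id": req.design_id, "error": "no guides found"}]
    return rows


def donor_genbank_record(res: DesignResult) -> SeqRecord:
    """Annotated GenBank record for one donor: arms, payload, guide,
    recoded bases and exon structure."""
    d = res.donor
    seq = d.seq_plus
    rec = SeqRecord(Seq(seq), id=res.request.design_id[:16], name=res.request.design_id[:16],
                    description=f"HDR donor ({d.mode}, reported strand {d.strand})")
    rec.annotations["molecule_type"] = "ss-DNA" if d.mode == "ssODN" else "ds-DNA"
    p5, p3 = d.payload_span
    off = d.trim5
    hi = len(d.full_seq) - d.trim3

    def add(lo, hi_, ftype, label, extra=None):
        lo, hi_ = max(lo, off), min(hi_, hi)
        if lo >= hi_:
            return
        q = {"label": [label]}
        q.update(extra or {})
        rec.features.append(
            SeqFeature(FeatureLocation(lo - off, hi_ - off), type=ftype, qualifiers=q)
        )

    add(off, p5, "misc_feature", "5' homology arm")
    add(p5, p3, "misc_feature", "payload")
    add(p3, hi, "misc_feature", "3' homology arm")
    for m in d.plan.mutations:
        add(m.offset, m.offset + 1, "variation",
            f"recoded {m.ref}>{m.alt} ({m.mclass}, {m.region})")
    g = d.guide
    if g is not None:
        lo, hi_ = d.donor_offset(g.start), d.donor_offset(g.end - 1) + 1
        add(lo, hi_, "misc_bind", f"protospacer ({g.strand})")
    if res.request.transcript_id:
        add(off, hi, "source", f"transcript context {res.request.transcript_id}")
    return rec


SUBMISSION_COLS = [
    "design_id", "target", "payload", "enzyme", "num_guides", "donor_mode",
    "arm5_len", "arm3_len", "ssodn_max_len", "recoding_level", "strand_mode",
    "trim_enabled", "min_arm_len", "forbidden_motifs", "cfd_threshold",
    "recut_priority", "coding_only", "position_weight", "primer_mode",
    "max_mismatches", "search_radius",
]


def write_outputs(results: list[DesignResult], out_dir) -> dict[str, Path]:
    """Write results.csv, the parameterized submission echo (itself a valid
    submission), one GenBank file per donor, and a per-design timing log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    all_cols = GUIDE_COLS + DONOR_COLS + PRIMER_COLS + ["error"]
    results_path = out / "results.csv"
    with open(results_path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=all_cols)
        w.writeheader()
        for res in results:
            for row in _result_rows(res):
                w.writerow({c: row.get(c, "") for c in all_cols})
    paths["results"] = results_path

    echo_path = out / "submission_echo.csv"
    with open(echo_path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=SUBMISSION_COLS)
        w.writeheader()
        for res in results:
            req = res.request
            row = {c: getattr(req, c, "") for c in SUBMISSION_COLS if c != "target"}
            row["target"] = req.target_string
            w.writerow(row)
    paths["submission_echo"] = echo_path

    for res in results:
        if res.donor is not None and not res.error:
            gb = out / f"{res.request.design_id}.gb"
            SeqIO.write([donor_genbank_record(res)], str(gb), "genbank")
            paths[f"genbank:{res.request.design_id}"] = gb

    log_path = out / "run.log"
    with open(log_path, "w") as fh:
        for res in results:
            status = "ERROR " + res.error if res.error else "ok"
            fh.write(f"{res.request.design_id}\t{res.elapsed:.3f}s\t{status}\n")
    paths["log"] = log_path
    return paths
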