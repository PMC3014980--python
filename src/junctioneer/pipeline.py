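"""Pipeline orchestration: compare alleles, call and classify junctions,
optionally map poly(A) sites, and write a deterministic report bundle.

The bundle contains a divergence-catalog TSV, an event-call JSON, BED
evidence tracks, an optional poly(A)-site TSV, and a manifest recording the
tool version, the effective configuration (hashed), and SHA-256 checksums of
every input.  Re-running with identical inputs and configuration reproduces
every table byte-for-byte; only the manifest carries a timestamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

from . import __version__
from .junction_forensics import (ClassifyParams, EventCall, call_junctions,
                                 classify_event)
from .locus_io import read_fasta, write_reports
from .pairwise_compare import AlignParams, divergence_catalog, global_align
from .polya_mapper import map_reads


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    ref_path: str
    alt_path: str
    out_dir: str
    te_lib_path: Optional[str] = None
    reads_path: Optional[str] = None
    utr_ref_path: Optional[str] = None
    stop_pos: Optional[int] = None       # 1-based position of first nt after stop
    align: AlignParams = field(default_factory=AlignParams)
    classify: ClassifyParams = field(default_factory=ClassifyParams)
    min_count: int = 2

    def __post_init__(self) -> None:
        for name in ("window", "min_frag", "min_sv_len"):
            if getattr(self.classify, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        for name, path in (("ref", self.ref_path), ("alt", self.alt_path),
                           ("te_lib", self.te_lib_path),
                           ("reads", self.reads_path),
                           ("utr_ref", self.utr_ref_path)):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} input not found: {path}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def event_to_row(event: EventCall) -> dict:
    j = event.junction
    row = {
        "kind": event.kind,
        "confidence": event.confidence,
        "ref_id": j.ref_id,
        "alt_id": j.alt_id,
        "ref_del_start": j.ref_del[0],
        "ref_del_end": j.ref_del[1],
        "del_len": j.del_len,
        "ins_len": len(j.alt_ins),
        "alt_ins": j.alt_ins if len(j.alt_ins) <= 200 else j.alt_ins[:200] + "...",
        "alt_pos": j.alt_pos,
    }
    if event.tsd:
        row["tsd_seq"] = event.tsd.tsd_seq
        row["tsd_len"] = event.tsd.tsd_len
    if event.te_id:
        row["te_id"] = event.te_id
        row.update({f"te_{k}": v for k, v in event.notes.items()})
    if event.filler:
        row["filler_explained_frac"] = round(event.filler.explained_fraction, 4)
        row["filler_fragments"] = [
            {"seq": f.frag_seq, "len": f.frag_len, "side": f.donor_side,
             "offset": f.donor_offset, "strand": f.donor_strand}
            for f in event.filler.fragments
        ]
    if event.tandem_dup:
        row["dup_period"] = event.tandem_dup.period
        row["dup_anchor_len"] = event.tandem_dup.anchor_len
        row["dup_anchor_seq"] = event.tandem_dup.anchor_seq
    if event.flanking_repeat:
        row["flanking_repeat_len"] = event.flanking_repeat.repeat_seq_len
        row["flanking_repeat_identity_pct"] = round(
            event.flanking_repeat.identity_pct, 2
        )
    if "endpoint_anchor_len" in event.notes:
        row["endpoint_anchor_len"] = event.notes["endpoint_anchor_len"]
    return row


def analyze_pair(ref, alt, te_library=None, align_params=None,
                 classify_params=None):
    """Library-level core: align, catalog, call and classify junctions."""
    align_params = align_params or AlignParams()
    classify_params = classify_params or ClassifyParams()
    aln = global_align(ref, alt, align_params)
    if aln.unalignable:
        return aln, None, []
    catalog = divergence_catalog(aln)
    junctions = call_junctions(
        aln, classify_params.min_sv_len, classify_params.window,
        classify_params.merge_dist,
    )
    events = [
        classify_event(j, te_library, classify_params, ref_seq=aln.a)
        for j in junctions
    ]
    return aln, catalog, events


def run_pipeline(config: RunConfig) -> dict:
    """Run compare -> junction forensics -> (optional) poly-A mapping and
    write the report bundle into ``config.out_dir``.

    Returns a dict of output paths plus the in-memory results.  Any stage
    failure removes partial outputs and raises StageError naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        stage = "read_inputs"
        ref = read_fasta(config.ref_path)[0]
        alt = read_fasta(config.alt_path)[0]
        te_library = (read_fasta(config.te_lib_path)
                      if config.te_lib_path else None)

        stage = "compare"
        aln, catalog, events = analyze_pair(
            ref, alt, te_library, config.align, config.classify
        )
        catalog_path = out / "divergence_catalog.tsv"
        if catalog is not None:
            write_reports(
                [
                    {
                        "ref_id": ref.id, "alt_id": alt.id,
                        "n_snps": catalog.n_snps, "n_indels": catalog.n_indels,
                        "indel_lengths": list(catalog.indel_lengths),
                        "consensus_length": catalog.consensus_length,
                        "identity_pct": round(catalog.identity_pct, 4),
                    }
                ],
                catalog_path, "TSV",
                columns=["ref_id", "alt_id", "n_snps", "n_indels",
                         "indel_lengths", "consensus_length", "identity_pct"],
            )
        else:
            write_reports([], catalog_path, "TSV",
                          columns=["ref_id", "alt_id", "n_snps", "n_indels",
                                   "indel_lengths", "consensus_length",
                                   "identity_pct"])
        written.append(catalog_path)

        stage = "junctions"
        events_path = out / "events.json"
        write_reports([event_to_row(e) for e in events], events_path, "JSON")
        written.append(events_path)
        bed_path = out / "evidence.bed"
        write_reports(
            [
                {"seq_id": e.junction.ref_id, "start": e.junction.ref_del[0],
                 "end": max(e.junction.ref_del[1], e.junction.ref_del[0] + 1),
                 "name": e.kind, "strand": "."}
                for e in events
            ],
            bed_path, "BED",
        )
        written.append(bed_path)

        results: dict = {
            "alignment": aln, "catalog": catalog, "events": events,
            "paths": {"catalog": str(catalog_path), "events": str(events_path),
                      "evidence": str(bed_path)},
        }

        if config.reads_path and config.utr_ref_path and config.stop_pos:
            stage = "polya"
            reads = [(r.id, r.seq) for r in read_fasta(config.reads_path)]
            utr = read_fasta(config.utr_ref_path)[0]
            table, rejected = map_reads(
                reads, utr, config.stop_pos - 1, min_count=config.min_count
            )
            polya_path = out / "polya_sites.tsv"
            write_reports(
                [
                    {"pos_after_stop": s.pos_after_stop, "count": s.count,
                     "fraction_pct": round(s.fraction, 4),
                     "feature_overlap": s.feature_overlap}
                    for s in table.reported_sites
                ],
                polya_path, "TSV",
                columns=["pos_after_stop", "count", "fraction_pct",
                         "feature_overlap"],
            )
            written.append(polya_path)
            results["polya_table"] = table
            results["polya_rejected"] = rejected
            results["paths"]["polya"] = str(polya_path)

        stage = "manifest"
        cfg_dict = dataclasses.asdict(config)
        manifest = {
            "tool": "junctioneer",
            "version": __version__,
            "created_utc": datetime.now(timezone.utc).isoformat(),
            "config": cfg_dict,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg_dict, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "input_checksums": {
                str(p): _sha256(p)
                for p in [config.ref_path, config.alt_path, config.te_lib_path,
                          config.reads_path, config.utr_ref_path]
                if p is not None
            },
        }
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                            default=str) + "\n")
        results["paths"]["manifest"] = str(manifest_path)
        return results
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc
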