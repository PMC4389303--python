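"""End-to-end orchestration: simulate -> finish -> structure -> variants
-> HGT verification -> matrix, with a plain-text config and a
machine-readable summary that is byte-identical for identical
(config, seed).
"""
from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import hgt, io, published, structure, synthetic, variants
from . import seq as sq
from .finishing import assess_assembly, close_gaps, scaffold_contigs
from .matrixbuild import (assemble_matrix, extract_coding, mask_inversions,
                          reference_guided_msa, strip_gapped_columns)

ALL_STAGES = ("simulate", "finish", "canonicalize", "annotate",
              "variants", "hgt", "matrix")


@dataclass
class RunConfig:
    """Parameters of a full demonstration run (all stages seeded)."""

    seed: int = 1
    outdir: str = "plastomekit_run"
    stages: tuple[str, ...] = ALL_STAGES
    # genome spec
    lsc_len: int = 81_000
    ssc_len: int = 12_900
    ir_len: int = 21_800
    at_fraction: float = 0.61
    insert_at_fraction: float = 0.55
    # reads
    coverage: float = 30.0
    read_len: int = 100
    pairing: str = "single"
    error_rate: float = 0.0
    # stage parameters
    min_overlap: int = 20
    min_similarity: float = 0.70
    min_ir_len: int = 1000
    min_indel: int = 100
    min_inversion: int = 50
    anchor_k: int = 21

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["stages"] = list(self.stages)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def config_hash(self) -> str:
        d = asdict(self)
        d["stages"] = list(self.stages)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the summary.

    Artifacts are written under ``config.outdir``; the summary (also
    written as summary.json) carries the config hash and seed so runs
    are traceable and reproducible.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2**31)
    summary: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                     "stages": {}}
    state: dict = {}

    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        fn = _STAGES[stage]
        summary["stages"][stage] = fn(config, state, out, seeds)
        _log(f"[plastomekit] stage {stage} done in "
             f"{time.perf_counter() - t0:.1f} s")

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _stage_simulate(cfg: RunConfig, state: dict, out: Path, seeds) -> dict:
    spec = synthetic.PlastomeSpec(
        lsc_len=cfg.lsc_len, ssc_len=cfg.ssc_len, ir_len=cfg.ir_len,
        at_fraction=cfg.at_fraction, seed=int(seeds[0]))
    reference = synthetic.generate_plastome(spec)
    reference.name = "reference"

    # a mitochondrial-like donor provides the foreign insert payload
    rng = np.random.default_rng(int(seeds[1]))
    mito = sq.random_dna(12_000, cfg.insert_at_fraction, rng)
    payload = sq.mutate(mito[3_000:3_000 + 2_706], 0.01, rng)
    vspecs = [
        synthetic.VariantSpec("insertion", "rpl23-ndhB", 2706, payload=payload),
        synthetic.VariantSpec("insertion", "rps16-trnQ", 500,
                              payload_at_fraction=cfg.insert_at_fraction),
        synthetic.VariantSpec("inversion", "trnD-psbM", 150,
                              flank_repeat="CCYTTTTY"),
    ]
    sample, truth = synthetic.plant_variants(reference, vspecs,
                                             seed=int(seeds[2]))
    sample.name = "sample"
    reads = synthetic.simulate_reads(
        sample, coverage=cfg.coverage, read_len=cfg.read_len,
        pairing=cfg.pairing, error_rate=cfg.error_rate, seed=int(seeds[3]))
    contigs = synthetic.fragment_plastome(sample, "at_IR_boundaries")

    io.write_fasta(out / "reference.fasta", {reference.name: reference.sequence})
    io.write_gff3(out / "reference.gff3", reference)
    io.write_fasta(out / "sample_truth.fasta", {sample.name: sample.sequence})
    io.write_fastq(out / "reads.fastq", reads)
    io.write_contigs_fasta(out / "contigs.fasta", contigs)
    io.write_variants_tsv(out / "truth_variants.tsv", truth)

    state.update(reference=reference, sample=sample, reads=reads,
                 contigs=contigs, truth=truth, mito=mito)
    return {"genome_len": len(sample), "n_reads": len(reads),
            "n_contigs": len(contigs), "n_truth_variants": len(truth)}


def _stage_finish(cfg: RunConfig, state: dict, out: Path, seeds) -> dict:
    scaffold = scaffold_contigs(state["contigs"], state["sample"])
    result = close_gaps(scaffold, state["contigs"], state["reads"],
                        min_overlap=cfg.min_overlap)
    report = assess_assembly(result.plastome, state["reads"])
    io.write_fasta(out / "finished.fasta",
                   {"finished": result.plastome.sequence})
    state.update(finished=result.plastome, assembly_report=report)
    return {"closed": result.closed,
            "open_gaps": result.open_gaps,
            "mean_depth": round(report.mean_depth, 2),
            "n_inconsistencies": len(report.inconsistencies),
            "identical_to_truth": sq.circularly_equal(result.plastome.sequence,
                                           state["sample"].sequence)}


def _stage_canonicalize(cfg: RunConfig, state: dict, out: Path, seeds) -> dict:
    finished = state.get("finished", state["sample"])
    canonical = structure.canonicalize(finished, min_ir_len=cfg.min_ir_len)
    if canonical.regions is None:
        return {"no_ir": True}
    state["canonical"] = canonical
    rl = canonical.region_lengths()
    table = structure.region_table({"finished": canonical})
    table.to_csv(out / "region_table.tsv", sep="\t", index=False)
    return {"total_len": len(canonical), "lsc_len": rl["LSC"],
            "ssc_len": rl["SSC"], "ir_len": rl["IRb"]}


def _stage_annotate(cfg: RunConfig, state: dict, out: Path, seeds) -> dict:
    canonical = state.get("canonical", state["sample"])
    rep = structure.transfer_annotations(canonical, state["reference"],
                                         min_similarity=cfg.min_similarity)
    # with the marker gene now annotated, fix the canonical strand choice
    annotated = structure.canonicalize(rep.plastome, min_ir_len=cfg.min_ir_len)
    io.write_gff3(out / "finished.gff3", annotated)
    state["annotated"] = annotated
    return {"n_transferred": len(rep.transferred),
            "n_untransferred": len(rep.untransferred)}


def _stage_variants(cfg: RunConfig, state: dict, out: Path, seeds) -> dict:
    ref = state["reference"]
    query = state.get("annotated", state.get("canonical", state["sample"]))
    chain = variants.anchor_align(query.sequence, ref.sequence, k=cfg.anchor_k)
    indels = variants.detect_indels(chain, ref.features, min_len=cfg.min_indel)
    invs = variants.detect_inversions(query.sequence, ref.sequence,
                                      min_len=cfg.min_inversion,
                                      k=cfg.anchor_k, annotations=ref.features,
                                      chain=chain)
    flanked = []
    for r in invs:
        f, motifs = variants.find_inverted_flanks(query.sequence,
                                                  (r.start, r.end))
        flanked.append(variants.VariantRecord(
            kind=r.kind, locus=r.locus, start=r.start, end=r.end,
            length=r.length, taxa=r.taxa, flank_repeat_len=f,
            ref_start=r.ref_start, ref_end=r.ref_end))
    detected = indels + flanked
    io.write_variants_tsv(out / "detected_variants.tsv", detected)

    # synapomorphy mapping of the published marker events on the demo tree
    assignments = variants.map_synapomorphies(
        published.marker_event_records(), published.demo_tree_newick())
    recovery = _recovery_table(state["truth"], detected)
    state.update(detected=detected, chain=chain)
    return {"detected": [
                {"kind": r.kind, "locus": r.locus, "length": r.length,
                 "start": r.start, "end": r.end,
                 "flank_repeat_len": r.flank_repeat_len}
                for r in detected],
            "recovery": recovery,
            "synapomorphies": [
                {"event": a.record.locus, "kind": a.record.kind,
                 "status": a.status, "n_clade": len(a.clade)}
                for a in assignments]}


def _recovery_table(truth, detected) -> dict:
    found = 0
    rows = []
    for t in truth:
        match = next((d for d in detected
                      if d.kind == t.kind and d.length == t.length
                      and abs(d.start - t.start) <= 2), None)
        rows.append({"kind": t.kind, "locus": t.locus, "length": t.length,
                     "recovered": match is not None})
        if match is not None:
            found += 1
    return {"events": rows, "n_truth": len(truth), "n_recovered": found}


def _stage_hgt(cfg: RunConfig, state: dict, out: Path, seeds) -> dict:
    sample = state["sample"]
    insert = next(r for r in state["truth"]
                  if r.kind == "insertion" and r.length == 2706)
    interval = (insert.start, insert.end)
    rng = np.random.default_rng(int(seeds[4]))
    plastid_panel = {"plastid_decoy": sq.random_dna(20_000, cfg.at_fraction, rng)}
    mito_panel = {"mito_donor": state["mito"]}
    call = hgt.classify_insert_origin(
        sample.sequence[insert.start:insert.end], plastid_panel, mito_panel)

    report = state.get("assembly_report")
    if report is None:
        report = assess_assembly(sample, state["reads"])
    junction = hgt.junction_coverage(report, interval)
    at_ins, at_rest = hgt.composition_contrast(sample.sequence, interval)

    # junction-spanning primer pair: amplifies across the upstream boundary
    fwd_start = insert.start - 1200
    fwd = sample.sequence[fwd_start:fwd_start + 25]
    rev5 = insert.start + 1199
    rev = sq.revcomp(sample.sequence[rev5 - 24:rev5 + 1])
    products = hgt.insilico_pcr(sample.sequence,
                                hgt.PrimerPair(fwd, rev, max_product=3000))
    result = {
        "origin_call": call.best_source,
        "origin_identity": round(call.identity, 4),
        "junction": {
            "depth_ratio_up": round(junction.depth_ratio_up, 3),
            "depth_ratio_down": round(junction.depth_ratio_down, 3),
            "suspect": junction.upstream_suspect or junction.downstream_suspect,
        },
        "at_insert": round(at_ins, 4),
        "at_rest": round(at_rest, 4),
        "pcr_product_lengths": sorted(p.length for p in products),
    }
    with open(out / "hgt_report.json", "w") as fh:
        json.dump(result, fh, indent=2, sort_keys=True)
    return result


def _stage_matrix(cfg: RunConfig, state: dict, out: Path, seeds) -> dict:
    ref = state["reference"]
    sample = state["sample"]
    # build the matrix over the canonical circle with IRa excluded
    ira = ref.region("IRa")
    ref_noira = ref.sequence[:ira[0]]
    sam_ira = sample.region("IRa") if sample.regions else None
    sample_noira = (sample.sequence[:sam_ira[0]] if sam_ira
                    else sample.sequence)
    msa = reference_guided_msa(ref_noira, {"sample": sample_noira},
                               ref_name="reference", k=cfg.anchor_k)
    feats = [f for f in ref.features if f.end <= ira[0]]
    matrix = assemble_matrix(msa, feats, ref_taxon="reference")
    inv_records = [r for r in state.get("detected", []) if r.kind == "inversion"]
    masked = mask_inversions(matrix, inv_records, ref_taxon="reference")
    stripped = strip_gapped_columns(masked)
    coding = extract_coding(stripped, ref_taxon="reference")
    stripped.to_fasta(out / "matrix_stripped.fasta")
    stripped.to_phylip(out / "matrix_stripped.phy")
    stripped.write_partitions(out / "partitions.txt")
    coding.to_fasta(out / "matrix_coding.fasta")
    return {"aligned_cols": matrix.n_columns,
            "after_inversion_mask": masked.n_columns,
            "after_gap_strip": stripped.n_columns,
            "coding_cols": coding.n_columns}


_STAGES = {
    "simulate": _stage_simulate,
    "finish": _stage_finish,
    "canonicalize": _stage_canonicalize,
    "annotate": _stage_annotate,
    "variants": _stage_variants,
    "hgt": _stage_hgt,
    "matrix": _stage_matrix,
}
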