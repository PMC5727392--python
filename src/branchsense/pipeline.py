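"""End-to-end pipeline: simulate -> features -> quantify -> compare.

Orchestrates one reproducible run from a single JSON config: generate (or
load) inputs, score 3'ss sequence features, quantify PSI/PIR and classify
events, run the group comparisons, RNA maps and (for multi-drug runs)
cross-drug overlap/enrichment/clustering, and write a manifest.  All
outputs are TSV/FASTA/BED; a rerun with the same config and seed
reproduces every table byte for byte (only manifest timestamps differ).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import io_formats, group_stats, splice_quant, ss_features
from .io_formats import IntronRecord, read_pwm, sf1_pwm
from .synthetic_data import DrugSpec, SimParams, generate_event_set
from ._version import __version__

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "report",
           "compute_features", "DEFAULT_CONFIG"]

log = logging.getLogger("branchsense")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "out_dir": "branchsense_run",
    "sim": {"n_events": 300, "ir_fraction": 0.5},
    "drugs": None,              # e.g. [{"name": "SSA", "delta_max": 60}, ...]
    "bp_window": 150,
    "multi_bp_window": 100,
    "pwm": None,                # optional PWM TSV path; default SF1 consensus
    "control": None,            # sample lists; default CTRL_*/TRT_* from sim
    "treated": None,
    "min_reads": 10,
    "regulated_threshold": 25.0,
    "nondiff_threshold": 5.0,
    "rnamap_pattern": "YNYYRAY",
    "rnamap_width": 100,
    "rnamap_smooth": 15,
}


@dataclass
class PipelineConfig:
    """Validated run configuration (flat JSON on disk)."""

    values: dict[str, Any]

    @classmethod
    def load(cls, source: str | Path | Mapping[str, Any]) -> "PipelineConfig":
        if isinstance(source, (str, Path)):
            with open(source) as fh:
                user = json.load(fh)
        else:
            user = dict(source)
        unknown = sorted(set(user) - set(DEFAULT_CONFIG))
        if unknown:
            raise ValueError(f"unknown config key(s): {unknown}")
        merged = {**DEFAULT_CONFIG, **user}
        if "sim" in user:
            merged["sim"] = {**DEFAULT_CONFIG["sim"], **user["sim"]}
        errors = []
        if not isinstance(merged["seed"], int):
            errors.append("seed: must be an integer")
        for key in ("min_reads", "bp_window", "multi_bp_window",
                    "rnamap_width", "rnamap_smooth"):
            if not isinstance(merged[key], int) or merged[key] < 1:
                errors.append(f"{key}: must be a positive integer")
        if errors:
            raise ValueError("config validation failed: " + "; ".join(errors))
        return cls(values=merged)

    def __getitem__(self, key: str) -> Any:
        return self.values[key]


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    version: str
    config: dict[str, Any]
    seed: int
    outputs: dict[str, str] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)
    timestamps: dict[str, str] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def compute_features(introns: list[IntronRecord], pwm=None,
                     bp_window: int = 150, multi_bp_window: int = 100) -> pd.DataFrame:
    """Score every intron; returns one row per event (EVENT_ID = intron name)."""
    if pwm is None:
        pwm = sf1_pwm()
    rows = []
    for rec in introns:
        fv = ss_features.score_intron(rec, pwm, bp_window=bp_window,
                                      multi_bp_window=multi_bp_window)
        rows.append({"EVENT_ID": rec.name, **fv.as_dict()})
    return pd.DataFrame(rows)


def run_pipeline(config: str | Path | Mapping[str, Any],
                 out_dir: str | Path | None = None) -> RunManifest:
    """Run the full pipeline from a config; returns the manifest.

    Stages: simulate (FASTA/BED/event tables/truth), features, quantify &
    classify, compare (feature and multi-BP comparisons, expression
    correlation, RNA map) and, when more than one drug is configured,
    overlap/enrichment/heatmap ordering.
    """
    cfg = PipelineConfig.load(config)
    out = Path(out_dir if out_dir is not None else cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, config=cfg.values, seed=cfg["seed"])

    def record(stage: str, path: Path) -> None:
        manifest.outputs[path.name] = str(path)
        manifest.checksums[path.name] = _sha256(path)
        manifest.timestamps.setdefault(stage, time.strftime("%Y-%m-%dT%H:%M:%S"))

    # ------------------------------------------------------------- simulate
    t0 = time.time()
    params = SimParams(seed=cfg["seed"], **cfg["sim"])
    drugs = None
    if cfg["drugs"]:
        drugs = [DrugSpec(name=d["name"], delta_max=d["delta_max"],
                          beta=tuple(d["beta"]) if d.get("beta") else None)
                 for d in cfg["drugs"]]
    sim = generate_event_set(params, drugs=drugs)
    io_formats.write_fasta(out / "genome.fa", sim.chromosomes)
    io_formats.write_bed_introns(out / "introns.bed", sim.introns)
    _write_tsv(sim.truth, out / "truth.tsv")
    for name, table in sim.tables.items():
        io_formats.write_event_table(out / f"events_{name}.tsv", table)
    for p in sorted(out.glob("*")):
        if p.suffix in (".fa", ".bed") or p.name.startswith(("events_", "truth")):
            record("simulate", p)
    log.info("simulate: %d events, %d drug(s) [%.1fs]",
             len(sim.truth), len(sim.tables), time.time() - t0)

    # ------------------------------------------------------------- features
    t0 = time.time()
    fasta = io_formats.read_fasta(out / "genome.fa")
    introns = io_formats.read_bed_introns(out / "introns.bed", fasta)
    pwm = read_pwm(cfg["pwm"]) if cfg["pwm"] else sf1_pwm()
    features = compute_features(introns, pwm, cfg["bp_window"], cfg["multi_bp_window"])
    _write_tsv(features, out / "features.tsv")
    record("features", out / "features.tsv")
    log.info("features: %d introns scored [%.1fs]", len(features), time.time() - t0)

    # ------------------------------------------------- quantify and classify
    t0 = time.time()
    control = cfg["control"] or [f"CTRL_{i + 1}" for i in range(params.n_replicates)]
    treated = cfg["treated"] or [f"TRT_{i + 1}" for i in range(params.n_replicates)]
    quantified: dict[str, pd.DataFrame] = {}
    for name, table in sim.tables.items():
        q = splice_quant.quantify(table, control, treated,
                                  min_reads=cfg["min_reads"],
                                  regulated_threshold=cfg["regulated_threshold"],
                                  nondiff_threshold=cfg["nondiff_threshold"])
        quantified[name] = q
        _write_tsv(q, out / f"psi_{name}.tsv")
        record("quantify", out / f"psi_{name}.tsv")
        counts = q["event_class"].value_counts()
        log.info("quantify[%s]: %s [%.1fs]", name,
                 ", ".join(f"{k}={v}" for k, v in counts.items()), time.time() - t0)

    # -------------------------------------------------------------- compare
    t0 = time.time()
    first = next(iter(sim.tables))
    q = quantified[first].set_index("EVENT_ID")
    feats = features.set_index("EVENT_ID").join(q[["TYPE", "delta", "event_class"]],
                                                rsuffix="_q")
    comparisons = []
    for etype, reg_class in (("IR", "regulated_up"), ("CE", "regulated_down")):
        sub = feats[feats["TYPE"] == etype]
        if {reg_class, "nondiff"} <= set(sub["event_class"]):
            cmp = group_stats.compare_features(
                sub.drop(columns=["TYPE", "delta", "event_class"]),
                sub["event_class"], reg_class, "nondiff")
            cmp.insert(0, "event_type", etype)
            comparisons.append(cmp)
    comparisons_df = (pd.concat(comparisons, ignore_index=True)
                      if comparisons else pd.DataFrame())
    _write_tsv(comparisons_df, out / "comparisons.tsv")
    record("compare", out / "comparisons.tsv")

    # multi-BP protection: delta of single- vs multi-BP events (covered only)
    multi_rows = []
    for etype in ("IR", "CE"):
        sub = feats[(feats["TYPE"] == etype) & feats["delta"].notna()]
        resp = sub["delta"] if etype == "IR" else -sub["delta"]
        single = resp[sub["n_bp_matches_100"] == 1]
        multi = resp[sub["n_bp_matches_100"] >= 2]
        if len(single) >= 2 and len(multi) >= 2:
            cmp = group_stats.mann_whitney_u(multi, single, feature=f"delta_{etype}")
            multi_rows.append({
                "event_type": etype, "n_multi": cmp.n1, "n_single": cmp.n2,
                "median_delta_multi": cmp.median1, "median_delta_single": cmp.median2,
                "U": cmp.u_statistic, "p_value": cmp.p_value, "stars": cmp.stars,
            })
    _write_tsv(pd.DataFrame(multi_rows), out / "multi_bp.tsv")
    record("compare", out / "multi_bp.tsv")

    # expression vs splicing correlation
    fpkm = sim.tables[first].df.set_index("EVENT_ID")[f"FPKM_{treated[0]}"]
    joined = q.join(fpkm).dropna(subset=["delta", f"FPKM_{treated[0]}"])
    corr_rows = []
    for etype in ("IR", "CE"):
        sub = joined[joined["TYPE"] == etype]
        if len(sub) >= 3:
            r = group_stats.expr_splicing_correlation(sub["delta"].abs(),
                                                      sub[f"FPKM_{treated[0]}"])
            corr_rows.append({"event_type": etype, "n": len(sub), "pearson_r": r})
    _write_tsv(pd.DataFrame(corr_rows), out / "expr_correlation.tsv")
    record("compare", out / "expr_correlation.tsv")
    log.info("compare: %d feature comparisons [%.1fs]",
             len(comparisons_df), time.time() - t0)

    # --------------------------------------------------------------- rnamap
    t0 = time.time()
    by_id = {rec.name: rec for rec in introns}
    groups: dict[str, list[str]] = {}
    for cls in ("regulated_up", "regulated_down", "nondiff"):
        ids = q.index[q["event_class"] == cls]
        seqs = [io_formats.three_prime_region(by_id[i], cfg["rnamap_width"])
                for i in ids if i in by_id]
        if seqs:
            groups[cls] = seqs
    if len(groups) >= 2:
        profile = group_stats.rna_map(groups, cfg["rnamap_pattern"],
                                      width=cfg["rnamap_width"],
                                      smooth=cfg["rnamap_smooth"])
        _write_tsv(profile.to_frame(), out / "rnamap.tsv")
        record("rnamap", out / "rnamap.tsv")
    log.info("rnamap: %d groups [%.1fs]", len(groups), time.time() - t0)

    # -------------------------------------------- cross-drug (Fig 6 analogs)
    if len(sim.tables) >= 2:
        t0 = time.time()
        sets = splice_quant.regulated_sets(quantified)
        flat = {d: s["regulated"] for d, s in sets.items()}
        ov = group_stats.overlap_matrix(flat)
        region_rows = [{"region": "+".join(k), "count": v}
                       for k, v in sorted(ov.region_counts.items())]
        pct = ov.pct_shared.reset_index(names="set")
        _write_tsv(pd.DataFrame(region_rows), out / "overlap_regions.tsv")
        _write_tsv(pct, out / "overlap_pct.tsv")
        record("overlap", out / "overlap_regions.tsv")
        record("overlap", out / "overlap_pct.tsv")

        universe = len(sim.truth)
        ref_drug = sorted(flat)[0]
        enrich_rows = []
        for d in sorted(flat):
            if d == ref_drug:
                continue
            chi2, p = group_stats.chi2_2x2(len(flat[d]), universe,
                                           len(flat[ref_drug]), universe)
            enrich_rows.append({"drug": d, "reference": ref_drug,
                                "regulated": len(flat[d]),
                                "regulated_ref": len(flat[ref_drug]),
                                "universe": universe, "chi2": chi2, "p_value": p,
                                "stars": group_stats.significance_stars(p)})
        _write_tsv(pd.DataFrame(enrich_rows), out / "enrichment.tsv")
        record("overlap", out / "enrichment.tsv")

        delta_mat = pd.DataFrame({d: quantified[d].set_index("EVENT_ID")["delta"]
                                  for d in sorted(quantified)})
        regulated_any = sorted(set.union(*flat.values()))
        delta_mat = delta_mat.loc[delta_mat.index.intersection(regulated_any)]
        order = group_stats.heatmap_order(delta_mat)
        ordered = delta_mat.iloc[order.row_order, order.col_order].reset_index()
        _write_tsv(ordered, out / "heatmap.tsv")
        record("overlap", out / "heatmap.tsv")
        log.info("overlap: %d drugs, %d clustered events [%.1fs]",
                 len(flat), len(ordered), time.time() - t0)

    manifest.save(out / "manifest.json")
    return manifest


def report(manifest: RunManifest | str | Path) -> str:
    """Human-readable summary of a completed run (also writes report.txt)."""
    if not isinstance(manifest, RunManifest):
        manifest = RunManifest.load(manifest)
    missing = [n for n, p in manifest.outputs.items() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run: missing outputs {missing}")
    out = Path(next(iter(manifest.outputs.values()))).parent
    lines = [f"branchsense {manifest.version} run report (seed {manifest.seed})", ""]

    for name in sorted(manifest.outputs):
        if name.startswith("psi_"):
            q = pd.read_csv(manifest.outputs[name], sep="\t")
            counts = q["event_class"].value_counts().to_dict()
            drug = name[len("psi_"):-len(".tsv")]
            lines.append(f"[{drug}] event classes: " +
                         ", ".join(f"{k}={v}" for k, v in sorted(counts.items())))
    lines.append("")

    cmp_path = manifest.outputs.get("comparisons.tsv")
    if cmp_path:
        cmp = pd.read_csv(cmp_path, sep="\t")
        lines.append("feature comparisons (regulated vs nondiff, Mann-Whitney):")
        if cmp.empty:
            lines.append("  n=0, no test run")
        for _, r in cmp.iterrows():
            lines.append(
                f"  {r['event_type']:>2} {r['feature']:<18} "
                f"median {r['median1']:.3g} vs {r['median2']:.3g}  "
                f"p={r['p_value']:.3g} {r['stars']}"
            )
    mb_path = manifest.outputs.get("multi_bp.tsv")
    if mb_path:
        mb = pd.read_csv(mb_path, sep="\t")
        lines.append("")
        lines.append("multi-BP protection (delta, multi vs single BP):")
        if mb.empty:
            lines.append("  n=0, no test run")
        for _, r in mb.iterrows():
            lines.append(
                f"  {r['event_type']:>2} median {r['median_delta_multi']:.3g} (multi) vs "
                f"{r['median_delta_single']:.3g} (single)  p={r['p_value']:.3g} {r['stars']}"
            )
    ov_path = manifest.outputs.get("overlap_pct.tsv")
    if ov_path:
        lines.append("")
        lines.append("cross-drug overlap (% of row set shared with column set):")
        lines.append(pd.read_csv(ov_path, sep="\t").to_string(index=False))

    text = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(text)
    return text
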