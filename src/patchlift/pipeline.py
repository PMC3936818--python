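"""End-to-end orchestration: simulate/ingest -> reconstruct -> lift ->
effects -> stats -> enrich, with a JSON run manifest.

The pipeline is configured by a small YAML file (see
:data:`CONFIG_SCHEMA`), writes plain-text TSV/JSON reports into a run
directory, and records a manifest with the parameters and SHA-256
checksums of every stage's inputs and outputs.  A rerun skips stages
whose recorded input checksums still match and whose outputs exist.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import __version__
from .effects import (
    classify_effects,
    call_deleterious,
    effect_table,
    read_score_table,
    transfer_statuses,
)
from .enrichment import read_go_annotation, results_table, run_sea
from .errors import PatchliftError, ValidationError
from .genome import read_fasta, write_fasta
from .gff import gene_models_from_gff, read_gff, write_gff
from .liftover import lift_annotation, write_lift_report
from .reconstruct import apply_variants
from .sdi_io import is_ambiguous, read_sdi
from .simulate import SimConfig, preset_config, write_fixture_bundle
from . import stats as st

log = logging.getLogger("patchlift")

CONFIG_SCHEMA = """\
# patchlift run configuration (YAML)
out_dir: <run directory>
seed: <int>                      # used by the simulate stage
simulate:                        # either this ...
  preset: default | paper-shaped
inputs:                          # ... or explicit inputs
  reference: <FASTA>
  annotation: <GFF3>
  variants: {A: <SDI>, B: <SDI>} # one or two varieties
  gene_classes: <TSV>            # optional: columns gene_class, gene
  scores: <TSV>                  # optional: columns gene, variant, score
  go: <TSV>                      # optional: columns gene, term
window: 5000                     # near-gene bp for upstream/downstream
merge_gap: 100                   # bp for merging variant clusters
alpha: 0.05                      # enrichment significance level
"""

_STAGES = ["ingest", "reconstruct", "lift", "effects", "stats", "enrich"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data: dict = {"version": __version__, "stages": {}}
        if path.exists():
            with open(path) as fh:
                self.data = json.load(fh)

    def stage_current(self, name: str, inputs: list[Path]) -> bool:
        entry = self.data["stages"].get(name)
        if entry is None:
            return False
        recorded = entry.get("inputs", {})
        current = {str(p): _sha256(p) for p in inputs if p.exists()}
        if recorded != current:
            return False
        return all(Path(p).exists() for p in entry.get("outputs", {}))

    def record(self, name: str, inputs: list[Path], outputs: list[Path], params: dict):
        self.data["stages"][name] = {
            "inputs": {str(p): _sha256(p) for p in inputs},
            "outputs": {str(p): _sha256(p) for p in outputs},
            "params": params,
        }
        self.save()

    def save(self) -> None:
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(config_path: str | Path) -> Path:
    """Run every stage described by the config; returns the run directory."""
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "out_dir" not in cfg:
        raise ValidationError("config must be a mapping with an out_dir key")
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")
    window = int(cfg.get("window", 5000))
    merge_gap = int(cfg.get("merge_gap", 100))
    alpha = float(cfg.get("alpha", 0.05))
    seed = int(cfg.get("seed", 0))

    # -- stage: ingest (simulate or reference inputs)
    if "simulate" in cfg:
        preset = cfg["simulate"].get("preset", "default")
        sim_dir = out / "inputs"
        stage_inputs: list[Path] = [Path(config_path)]
        if manifest.stage_current("ingest", stage_inputs):
            log.info("stage ingest: up to date, skipped")
            paths = {
                k: sim_dir / v
                for k, v in {
                    "reference": "reference.fasta",
                    "annotation": "annotation.gff3",
                    "A": "variety_A.sdi",
                    "B": "variety_B.sdi",
                    "go": "go_annotation.tsv",
                    "scores": "scores.tsv",
                }.items()
            }
            if (sim_dir / "gene_classes.tsv").exists():
                paths["gene_classes"] = sim_dir / "gene_classes.tsv"
        else:
            log.info("stage ingest: simulating preset %r (seed %d)", preset, seed)
            bundle_paths = write_fixture_bundle(
                preset_config(preset, seed=seed), sim_dir
            )
            paths = {
                "reference": bundle_paths["reference"],
                "annotation": bundle_paths["annotation"],
                "A": bundle_paths["variants_a"],
                "B": bundle_paths["variants_b"],
                "go": bundle_paths["go"],
                "scores": bundle_paths["scores"],
            }
            if "gene_classes" in bundle_paths:
                paths["gene_classes"] = bundle_paths["gene_classes"]
            manifest.record(
                "ingest", stage_inputs, sorted(paths.values()),
                {"preset": preset, "seed": seed},
            )
    else:
        inputs = cfg.get("inputs") or {}
        for key in ("reference", "annotation", "variants"):
            if key not in inputs:
                raise ValidationError(f"config inputs missing {key!r}")
        paths = {
            "reference": Path(inputs["reference"]),
            "annotation": Path(inputs["annotation"]),
        }
        for variety, sdi in inputs["variants"].items():
            paths[variety] = Path(sdi)
        for opt in ("gene_classes", "scores", "go"):
            if opt in inputs:
                paths[opt] = Path(inputs[opt])
        manifest.record("ingest", sorted(paths.values()), [], {"mode": "files"})

    varieties = [k for k in paths if k not in (
        "reference", "annotation", "go", "scores", "gene_classes")]
    reference = read_fasta(paths["reference"])
    models = gene_models_from_gff(paths["annotation"])

    # -- stage: reconstruct + lift + effects, per variety
    records = {}
    calls = {}
    for variety in varieties:
        records[variety] = read_sdi(paths[variety])
        fasta_out = out / f"genome_{variety}.fasta"
        chain_out = out / f"offsets_{variety}.chain"
        gff_out = out / f"annotation_{variety}.gff3"
        report_out = out / f"lift_report_{variety}.tsv"
        stage_inputs = [paths["reference"], paths[variety], paths["annotation"]]
        if manifest.stage_current(f"reconstruct:{variety}", stage_inputs) and \
           manifest.stage_current(f"lift:{variety}", stage_inputs):
            log.info("stages reconstruct/lift (%s): up to date, skipped", variety)
        else:
            log.info("stage reconstruct (%s): applying %d variants",
                     variety, len(records[variety]))
            variety_genome, offset_map = apply_variants(reference, records[variety])
            write_fasta(variety_genome, fasta_out)
            offset_map.write_chain(chain_out)
            manifest.record(
                f"reconstruct:{variety}", stage_inputs,
                [fasta_out, chain_out], {},
            )
            log.info("stage lift (%s)", variety)
            lifted, report = lift_annotation(read_gff(paths["annotation"]), offset_map)
            write_gff(lifted, gff_out)
            write_lift_report(report, report_out)
            manifest.record(
                f"lift:{variety}", stage_inputs, [gff_out, report_out], {},
            )
        log.info("stage effects (%s)", variety)
        calls[variety] = classify_effects(
            records[variety], models, reference, window=window
        )
        effects_out = out / f"effects_{variety}.tsv"
        effect_table(calls[variety]).to_csv(effects_out, sep="\t", index=False)
        statuses = transfer_statuses(calls[variety], models)
        transfer_out = out / f"transfer_{variety}.tsv"
        with open(transfer_out, "w") as fh:
            fh.write("gene\tstatus\n")
            for gid in sorted(statuses):
                fh.write(f"{gid}\t{statuses[gid].value}\n")
        manifest.record(
            f"effects:{variety}", stage_inputs, [effects_out, transfer_out],
            {"window": window},
        )

    # -- stage: stats
    log.info("stage stats")
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    summary: dict = {"varieties": varieties}
    chrom_lengths = {name: reference.length(name) for name in reference.names}
    for variety in varieties:
        recs = records[variety]
        table = st.variant_class_counts(recs)
        table.to_csv(stats_dir / f"class_counts_{variety}.tsv", sep="\t")
        st.feature_breakdown(calls[variety]).to_csv(
            stats_dir / f"feature_breakdown_{variety}.tsv", sep="\t", index=False
        )
        snps = [r for r in recs if len(r.ref_allele) == 1 and len(r.alt_allele) == 1]
        n_ambiguous = sum(1 for r in snps if is_ambiguous(r))
        statuses = transfer_statuses(calls[variety], models)
        tsum = st.transfer_summary(statuses, total_annotations=len(models))
        tsum.to_csv(stats_dir / f"transfer_summary_{variety}.tsv", sep="\t")
        summary[variety] = {
            "n_variants": len(recs),
            "n_snps": len(snps),
            "ambiguous_snp_fraction": n_ambiguous / len(snps) if snps else None,
            "n50_between_polymorphic_bp": st.n50_between(
                recs, chrom_lengths, merge_gap=merge_gap
            ),
            "not_transferred": int(tsum.loc["not_transferred", "count"]),
            "not_transferred_pct": float(tsum.loc["not_transferred", "percent"]),
        }
    if len(varieties) == 2:
        a, b = varieties
        common, a_only, b_only = st.shared_specific(records[a], records[b])
        summary["shared"] = {
            "common": len(common),
            f"{a}_only": len(a_only),
            f"{b}_only": len(b_only),
            f"shared_pct_of_{a}": st.shared_fraction(len(common), len(records[a])),
            f"shared_pct_of_{b}": st.shared_fraction(len(common), len(records[b])),
        }
        if "gene_classes" in paths:
            classes: dict[str, list[str]] = {}
            with open(paths["gene_classes"]) as fh:
                next(fh)
                for line in fh:
                    cls_name, gid = line.rstrip("\n").split("\t")
                    classes.setdefault(cls_name, []).append(gid)
            gct = st.gene_class_table(
                classes,
                {a: calls[a], b: calls[b]},
                {m.gene_id for m in models},
            )
            gct.to_csv(stats_dir / "gene_class_table.tsv", sep="\t")
    if "scores" in paths:
        scored, dsummary = call_deleterious(read_score_table(paths["scores"]))
        scored.to_csv(stats_dir / "deleterious.tsv", sep="\t", index=False)
        summary["deleterious"] = dsummary
    with open(stats_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest.record(
        "stats", [paths[v] for v in varieties], [stats_dir / "summary.json"],
        {"merge_gap": merge_gap},
    )

    # -- stage: enrich
    if "go" in paths and len(varieties) == 2:
        log.info("stage enrich")
        go = read_go_annotation(paths["go"])
        background = sorted(go)
        a, b = varieties
        study_sets = {}
        nonsyn = {"missense", "start_lost", "stop_lost", "stop_gained"}
        genes_a = {c.gene_id for c in calls[a] if c.effect in nonsyn}
        genes_b = {c.gene_id for c in calls[b] if c.effect in nonsyn}
        study_sets[a] = sorted((genes_a - genes_b) & set(background))
        study_sets[b] = sorted((genes_b - genes_a) & set(background))
        study_sets["common"] = sorted(genes_a & genes_b & set(background))
        enrich_outputs = []
        for label, study in study_sets.items():
            results = run_sea(study, background, go, alpha=alpha)
            path = out / f"enrichment_{label}.tsv"
            results_table(results).to_csv(path, sep="\t", index=False)
            enrich_outputs.append(path)
        manifest.record(
            "enrich", [paths["go"]], enrich_outputs, {"alpha": alpha},
        )
    manifest.save()
    log.info("run complete: %s", out)
    return out
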