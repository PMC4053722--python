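"""End-to-end orchestration: filter -> pileup -> normalize -> peaks ->
classification -> binding calls -> metagene -> enrichment suite, with a
deterministic JSON manifest (parameter echo, seeds, output checksums).

Inputs come either from files (reads, annotations, expression, regulation,
optional externally called peaks) or from the synthetic generator when the
config carries a ``simulate`` block, so the demo needs no input files at
all.  Rerunning with the same config reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .annotate import (
    BindingCallParams,
    ClassificationParams,
    bound_gene_ids,
    call_bound_genes,
    classify_peak_locations,
    write_binding_tsv,
    write_classification_tsv,
)
from .coverage import (
    AlignmentFilterParams,
    compile_repeat_coverage,
    filter_alignments,
    normalize_to_reference,
    pileup,
    start_pileup,
    write_bedgraph,
)
from .genome import AnnotationSet, GenomeLayout, load_annotations
from .metagene import MetageneParams, assign_quintiles, composite_profile, write_profile
from .peaks import (
    BinnedCallerParams,
    call_peaks_binned,
    filter_peaks_by_posterior,
    read_peaks_bed,
    write_peaks_bed,
)
from .reads import read_reads_bed, write_reads_bed
from .simulate import (
    FactorModel,
    SyntheticConfig,
    build_toy_genome,
    read_expression_tsv,
    read_regulation_tsv,
    simulate_expression,
    simulate_factor_reads,
    simulate_regulation_classes,
    write_expression_tsv,
    write_regulation_tsv,
)
from .stats import (
    fold_enrichment_random,
    multiway_overlap,
    regulation_association_test,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The pipeline configuration failed validation."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``demo_config`` for an example)."""

    seed: int = 0
    posterior_threshold: float = 0.5
    filter_params: AlignmentFilterParams = field(default_factory=AlignmentFilterParams)
    caller_params: BinnedCallerParams = field(default_factory=BinnedCallerParams)
    classification_params: ClassificationParams = field(default_factory=ClassificationParams)
    binding_params: BindingCallParams = field(default_factory=BindingCallParams)
    metagene_params: MetageneParams = field(default_factory=MetageneParams)
    n_perm: int = 1000
    simulate: SyntheticConfig | None = None
    factors: list[FactorModel] = field(default_factory=list)
    inputs: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(klass, key):
            return klass(**raw.get(key, {}))

        cfg = cls(
            seed=int(raw.get("seed", 0)),
            posterior_threshold=float(raw.get("posterior_threshold", 0.5)),
            filter_params=build(AlignmentFilterParams, "filter"),
            caller_params=build(BinnedCallerParams, "caller"),
            classification_params=build(ClassificationParams, "classification"),
            binding_params=build(BindingCallParams, "binding"),
            metagene_params=build(MetageneParams, "metagene"),
            n_perm=int(raw.get("enrichment", {}).get("n_perm", 1000)),
            inputs=dict(raw.get("inputs", {})),
        )
        if "simulate" in raw:
            sim = dict(raw["simulate"])
            factor_specs = sim.pop("factors", [{}])
            if "orf_length_range" in sim:
                sim["orf_length_range"] = tuple(sim["orf_length_range"])
            cfg.simulate = SyntheticConfig(**sim)
            for spec in factor_specs:
                spec = dict(spec)
                if spec.pop("null", False):
                    cfg.factors.append(
                        FactorModel.null(spec.get("factor_name", "null"))
                    )
                else:
                    if "orf_quintile_scaling" in spec:
                        spec["orf_quintile_scaling"] = tuple(spec["orf_quintile_scaling"])
                    cfg.factors.append(FactorModel(**spec))
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def validate(self) -> None:
        if self.simulate is None:
            required = ("chrom_sizes", "annotations", "reads")
            for key in required:
                if key not in self.inputs:
                    raise ConfigError(f"inputs.{key} is required without a simulate block")
            for key in ("chrom_sizes", "annotations", "expression", "regulation"):
                if key in self.inputs and not Path(self.inputs[key]).exists():
                    raise ConfigError(f"inputs.{key}: no such file {self.inputs[key]!r}")
            for factor, paths in self.inputs.get("reads", {}).items():
                for role, p in paths.items():
                    if not Path(p).exists():
                        raise ConfigError(
                            f"inputs.reads.{factor}.{role}: no such file {p!r}"
                        )
        elif not self.factors:
            raise ConfigError("simulate block needs at least one factor")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _factor_seed(base: int, i: int) -> int:
    return (base + 7919 * (i + 1)) % (2**31)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage and return the manifest (also written to
    ``manifest.json``).  All randomness derives from ``config.seed``."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package": "sirtchip",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "posterior_threshold": config.posterior_threshold,
            "filter": dataclasses.asdict(config.filter_params),
            "caller": dataclasses.asdict(config.caller_params),
            "classification": dataclasses.asdict(config.classification_params),
            "binding": dataclasses.asdict(config.binding_params),
            "metagene": dataclasses.asdict(config.metagene_params),
            "n_perm": config.n_perm,
        },
        "stages": [],
        "outputs": {},
        "complete": False,
    }
    if config.simulate is not None:
        manifest["parameters"]["simulate"] = dataclasses.asdict(config.simulate)
        manifest["parameters"]["factors"] = [
            dataclasses.asdict(f) for f in config.factors
        ]

    def record(stage: str, **info) -> None:
        logger.info("stage %s: %s", stage, info)
        manifest["stages"].append({"name": stage, **info})

    def emit(path: Path) -> None:
        manifest["outputs"][path.name] = _sha256(path)

    t0 = time.monotonic()
    try:
        # ---- inputs: simulate or load -------------------------------------
        if config.simulate is not None:
            sim = dataclasses.replace(config.simulate, seed=config.seed)
            layout, annots = build_toy_genome(sim)
            expr = simulate_expression(annots, sim, seed=_factor_seed(config.seed, 100))
            regulation = simulate_regulation_classes(
                annots, expr, sim, seed=_factor_seed(config.seed, 101)
            )
            layout.write_chrom_sizes(outdir / "genome.chrom.sizes")
            annots.write_bed(outdir / "annotations.bed")
            write_expression_tsv(expr, outdir / "expression.tsv")
            write_regulation_tsv(regulation, outdir / "regulation.tsv")
            for p in ("genome.chrom.sizes", "annotations.bed", "expression.tsv",
                      "regulation.tsv"):
                emit(outdir / p)
            reads = {}
            for i, model in enumerate(config.factors):
                chip, inp = simulate_factor_reads(
                    model, layout, annots, expr, sim, seed=_factor_seed(config.seed, i)
                )
                reads[model.factor_name] = {"chip": chip, "input": inp}
                write_reads_bed(chip, outdir / f"reads_{model.factor_name}_chip.bed")
                write_reads_bed(inp, outdir / f"reads_{model.factor_name}_input.bed")
                emit(outdir / f"reads_{model.factor_name}_chip.bed")
                emit(outdir / f"reads_{model.factor_name}_input.bed")
            record("simulate", n_factors=len(config.factors), n_features=len(annots))
        else:
            layout = GenomeLayout.from_chrom_sizes(config.inputs["chrom_sizes"])
            annots = load_annotations(
                config.inputs["annotations"],
                layout,
                format=config.inputs.get("annotation_format", "BED"),
                class_map=config.inputs.get("class_map"),
            )
            expr = (
                read_expression_tsv(config.inputs["expression"])
                if "expression" in config.inputs
                else None
            )
            regulation = (
                read_regulation_tsv(config.inputs["regulation"])
                if "regulation" in config.inputs
                else None
            )
            reads = {
                factor: {role: read_reads_bed(p) for role, p in paths.items()}
                for factor, paths in config.inputs["reads"].items()
            }
            record("load", n_factors=len(reads), n_features=len(annots))

        rdna = annots.features_of_class("rDNA_repeat")
        fparams = config.filter_params
        if rdna and not fparams.repeat_whitelist:
            fparams = dataclasses.replace(
                fparams, repeat_whitelist=tuple(f.interval for f in rdna)
            )

        # ---- filter + pileup + normalize ----------------------------------
        tracks, start_tracks, peak_sets = {}, {}, {}
        filtered = {}
        for factor, pair in reads.items():
            filtered[factor] = {
                role: filter_alignments(rs, fparams) for role, rs in pair.items()
            }
            record(
                f"filter[{factor}]",
                chip_kept=filtered[factor]["chip"].total_count,
                input_kept=filtered[factor]["input"].total_count,
            )
        reference_total = next(iter(filtered.values()))["chip"].total_count
        for factor, pair in filtered.items():
            chip_track = pileup(pair["chip"], layout)
            tracks[factor] = chip_track
            start_tracks[factor] = {
                role: start_pileup(rs, layout) for role, rs in pair.items()
            }
            norm = normalize_to_reference(chip_track, reference_total)
            write_bedgraph(norm, outdir / f"track_{factor}.bedgraph", name=factor)
            emit(outdir / f"track_{factor}.bedgraph")
            record(f"pileup[{factor}]", total_signal=chip_track.total_signal,
                   scale_factor=norm.scale_factor)
        if rdna:
            copies = 175
            if "copies=" in rdna[0].name:
                copies = int(rdna[0].name.split("copies=")[1])
            for factor, pair in filtered.items():
                profile = compile_repeat_coverage(pair["chip"], rdna[0], copies)
                record(f"rdna_profile[{factor}]", compiled_total=profile.total,
                       n_copies=copies)

        # ---- peaks: call or load, then posterior filter -------------------
        for factor in filtered:
            if "peaks" in config.inputs and factor in config.inputs["peaks"]:
                called = read_peaks_bed(config.inputs["peaks"][factor], factor)
            else:
                called = call_peaks_binned(
                    start_tracks[factor]["chip"],
                    start_tracks[factor]["input"],
                    config.caller_params,
                    factor_name=factor,
                )
            kept = filter_peaks_by_posterior(called, config.posterior_threshold)
            peak_sets[factor] = kept
            write_peaks_bed(kept, outdir / f"peaks_{factor}.bed")
            emit(outdir / f"peaks_{factor}.bed")
            emit(outdir / f"peaks_{factor}.bed.tsv")
            record(f"peaks[{factor}]", called=len(called), kept=len(kept))

        # ---- classification + binding calls -------------------------------
        bound = {}
        for factor, pset in peak_sets.items():
            classification = classify_peak_locations(
                pset, annots, config.classification_params
            )
            write_classification_tsv(
                classification, pset, outdir / f"classification_{factor}.tsv"
            )
            emit(outdir / f"classification_{factor}.tsv")
            calls = call_bound_genes(pset, annots, config.binding_params)
            write_binding_tsv(calls, outdir / f"binding_{factor}.tsv")
            emit(outdir / f"binding_{factor}.tsv")
            bound[factor] = bound_gene_ids(calls)
            record(
                f"classify[{factor}]",
                class_counts=classification.class_counts,
                n_embedded_orfs=len(classification.embedded_orfs),
                n_bound=len(bound[factor]),
            )

        # ---- metagene ------------------------------------------------------
        if expr is not None:
            quintiles = assign_quintiles(expr, config.metagene_params)
            for factor, track in tracks.items():
                prof = composite_profile(track, annots, quintiles, config.metagene_params)
                write_profile(prof, outdir / f"metagene_{factor}.tsv")
                emit(outdir / f"metagene_{factor}.tsv")
                emit(outdir / f"metagene_{factor}.tsv.json")
                record(f"metagene[{factor}]", n_genes=sum(prof.n_genes))

        # ---- enrichment suite ---------------------------------------------
        results = []
        tel = [f.interval for f in annots.features_of_class("telomeric_repeat")]
        pol3 = [f.interval for f in annots.features_of_class("pol3_gene")]
        factors = list(peak_sets)
        for i, factor in enumerate(factors):
            for fname, feats in (("telomeric_repeat", tel), ("pol3_gene", pol3)):
                if not feats or not len(peak_sets[factor]):
                    continue
                res = fold_enrichment_random(
                    peak_sets[factor], feats, layout, mode="feature_count",
                    n_perm=config.n_perm, seed=_factor_seed(config.seed, 200 + i),
                )
                results.append(
                    {"comparison": f"{factor}_vs_{fname}", **res.to_record()}
                )
        for i, a in enumerate(factors):
            for b in factors[i + 1:]:
                if not len(peak_sets[a]) or not len(peak_sets[b]):
                    continue
                res = fold_enrichment_random(
                    peak_sets[a], peak_sets[b].intervals, layout, mode="bp",
                    n_perm=config.n_perm, seed=_factor_seed(config.seed, 300 + i),
                )
                results.append({"comparison": f"{a}_peaks_vs_{b}_peaks", **res.to_record()})
        universe = {f.feature_id for f in annots.orfs}
        if len(factors) >= 2:
            venn = multiway_overlap({f: bound[f] for f in factors}, universe)
            results.append(
                {
                    "comparison": "bound_gene_overlap",
                    "regions": venn.region_counts,
                    "pairwise_p": {
                        f"{a}&{b}": r.p_value for (a, b), r in venn.pairwise.items()
                    },
                }
            )
        if regulation is not None:
            for factor in factors:
                assoc = regulation_association_test(bound[factor], regulation, universe)
                results.append(
                    {
                        "comparison": f"{factor}_regulation_association",
                        "classes": {
                            cls: {
                                "observed": a.observed,
                                "expected": a.expected,
                                "direction": a.direction,
                                "p_two_sided": a.p_two_sided,
                            }
                            for cls, a in assoc.items()
                        },
                    }
                )
        (outdir / "enrichment.json").write_text(
            json.dumps(results, sort_keys=True, indent=1) + "\n"
        )
        emit(outdir / "enrichment.json")
        with open(outdir / "enrichment_summary.tsv", "w") as fh:
            fh.write("comparison\tmode\tobserved\texpected\tfold\tempirical_p\n")
            for r in results:
                if "fold" in r:
                    fh.write(
                        f"{r['comparison']}\t{r['mode']}\t{r['observed']}\t"
                        f"{r['expected']!r}\t{r['fold']!r}\t{r['empirical_p']!r}\n"
                    )
        emit(outdir / "enrichment_summary.tsv")
        record("enrichment", n_comparisons=len(results))
        manifest["complete"] = True
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, sort_keys=True, indent=1) + "\n"
        )
        raise
    logger.info("pipeline finished in %.1fs", time.monotonic() - t0)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1) + "\n"
    )
    return manifest


def demo_config(seed: int = 7) -> PipelineConfig:
    """Self-contained two-factor demo: one coating factor with the full
    planted signal set and one null (Hst2-like) factor."""
    return PipelineConfig.from_dict(
        {
            "seed": seed,
            "simulate": {
                "n_chroms": 2,
                "chrom_length": 100_000,
                "n_orfs": 80,
                "orf_length_range": [500, 1500],
                "n_pol3": 8,
                "n_telomere_clusters": 4,
                "telomere_cluster_length": 300,
                "rdna_unit_length": 5000,
                "library_size": 60_000,
                "factors": [
                    {"factor_name": "sir2like"},
                    {"factor_name": "hst2like", "null": True},
                ],
            },
            "enrichment": {"n_perm": 500},
        }
    )
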