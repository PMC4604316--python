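"""Chains the analysis stages into one reproducible run.

Every report is TSV with a single ``#`` header line recording the tool
version, seed and thresholds; no timestamps are written, so two runs
with the same config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from .. import __version__
from ..carbon import (
    classify_group_bias,
    group_bias_table,
    group_partition,
    strain_substrate_counts,
    top_biased_compounds,
)
from ..consensus import similarity_table
from ..enrichment import enrichment_table
from ..errors import ConsistencyError
from ..pangenome import partition_compartments, presence_from_clusters, venn_report
from ..validation import reaction_venn, validate_predictions
from .config import RunConfig
from .formats import (
    read_alignment,
    read_compound_classes,
    read_labels,
    read_matrix,
    read_ortholog_groups,
    write_table,
)
from .types import COMPARTMENTS, CompartmentLabels, PresenceMatrix

logger = logging.getLogger(__name__)

import pandas as pd


def _header(config: RunConfig) -> str:
    return (
        f"rhizopan v{__version__} seed={config.seed} "
        f"pathway_alpha={config.pathway_alpha} "
        f"group_alpha={config.group_alpha} "
        f"permutations={config.permutations}"
    )


def _check_labelled(matrix: PresenceMatrix, labels: CompartmentLabels,
                    what: str) -> None:
    missing = [s for s in matrix.strains if s not in labels]
    if missing:
        raise ConsistencyError(
            f"strain(s) in the {what} matrix missing from the labels: "
            + ", ".join(sorted(missing))
        )


def run_full_analysis(config: RunConfig) -> dict[str, Path]:
    """Run every stage whose inputs are configured; returns the output
    paths keyed by report name."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = _header(config)
    outputs: dict[str, Path] = {}

    labels = read_labels(config.labels) if config.labels else None
    logger.info("run: seed=%d permutations=%d", config.seed,
                config.permutations)

    if config.groups:
        if labels is None:
            raise ConsistencyError("pan-genome stage requires labels")
        clusters = read_ortholog_groups(config.groups)
        unlabelled = [g for g in clusters.genomes if g not in labels]
        if unlabelled:
            raise ConsistencyError(
                "genome(s) in the groups file missing from the labels: "
                + ", ".join(sorted(unlabelled))
            )
        presence = presence_from_clusters(clusters, labels.strains)
        venn = partition_compartments(presence, labels)
        path = out / "pangenome_venn.tsv"
        write_table(venn_report(venn), path, header=header)
        outputs["pangenome_venn"] = path

    if config.alignment:
        aln = read_alignment(config.alignment)
        path = out / "consensus_similarity.tsv"
        write_table(similarity_table(aln), path, header=header,
                    float_format="%.1f")
        outputs["consensus_similarity"] = path

    if config.traits:
        if labels is None:
            raise ConsistencyError("trait enrichment stage requires labels")
        traits = read_matrix(config.traits, kind="trait")
        _check_labelled(traits, labels, "trait")
        table = enrichment_table(
            traits, labels, alpha=config.pathway_alpha,
            n_perm=config.permutations, seed=config.seed,
        )
        path = out / "trait_enrichment.tsv"
        write_table(table, path, header=header)
        outputs["trait_enrichment"] = path

    util = None
    if config.utilization:
        if labels is None:
            raise ConsistencyError("carbon stage requires labels")
        util = read_matrix(config.utilization, kind="utilization")
        _check_labelled(util, labels, "utilization")

        counts = strain_substrate_counts(util).reset_index()
        counts.columns = ["strain", "compounds_utilized"]
        path = out / "carbon_strain_counts.tsv"
        write_table(counts, path, header=header)
        outputs["carbon_strain_counts"] = path

        rows = []
        for comp in COMPARTMENTS:
            members = [s for s in util.strains if labels[s] == comp]
            if members:
                part = group_partition(util, members)
                rows.append(
                    {"group": comp, "n_all": part.n_all, "n_none": part.n_none,
                     "n_differential": part.n_differential,
                     "total": part.total}
                )
        part = group_partition(util, util.strains)
        rows.append(
            {"group": "panel", "n_all": part.n_all, "n_none": part.n_none,
             "n_differential": part.n_differential, "total": part.total}
        )
        path = out / "carbon_group_partition.tsv"
        write_table(pd.DataFrame(rows), path, header=header)
        outputs["carbon_group_partition"] = path

        if config.compound_classes:
            classes = read_compound_classes(config.compound_classes)
            bias = classify_group_bias(
                util, labels, classes, alpha=config.group_alpha,
                n_perm=config.permutations, seed=config.seed,
            )
            path = out / "carbon_group_bias.tsv"
            write_table(group_bias_table(bias), path, header=header)
            outputs["carbon_group_bias"] = path

        k = min(config.top_k, len(util.features))
        for comp in COMPARTMENTS:
            top = top_biased_compounds(util, labels, k, comp)
            path = out / f"carbon_top_{comp}.tsv"
            write_table(top, path, header=header)
            outputs[f"carbon_top_{comp}"] = path

    if config.predictions:
        if util is None:
            raise ConsistencyError(
                "model validation requires a utilization (observation) matrix"
            )
        pred = read_matrix(config.predictions, kind="prediction")
        report = validate_predictions(pred, util)
        path = out / "model_validation.tsv"
        write_table(report.to_frame(), path, header=header)
        outputs["model_validation"] = path
        path = out / "model_validation_summary.json"
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(report.summary(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        outputs["model_validation_summary"] = path

    if config.reactions:
        if labels is None:
            raise ConsistencyError("reaction stage requires labels")
        reactions = read_matrix(config.reactions, kind="presence")
        _check_labelled(reactions, labels, "reaction")
        rv = reaction_venn(reactions, labels)
        path = out / "reaction_venn.tsv"
        write_table(rv.to_frame(), path, header=header)
        outputs["reaction_venn"] = path

    return outputs


def simulate_bundle(truth, outdir, reactions: dict | None = None) -> dict[str, Path]:
    """Write a complete simulated input bundle plus its ground truth.

    Produces groups.txt, labels.tsv, alignment.fasta, traits.tsv,
    utilization.tsv, compound_classes.tsv, predictions.tsv, optionally
    reactions.tsv, a ready-to-run config.yaml and truth.json.
    """
    import dataclasses

    import yaml

    from ..simulate import (
        generate_alignment,
        generate_pangenome,
        generate_predictions,
        generate_traits,
        generate_utilization,
        plant_reaction_matrix,
    )
    from .formats import (
        write_alignment,
        write_compound_classes,
        write_labels,
        write_matrix,
        write_ortholog_groups,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    clusters, labels, _ = generate_pangenome(truth)
    write_ortholog_groups(clusters, outdir / "groups.txt")
    outputs["groups"] = outdir / "groups.txt"
    write_labels(labels, outdir / "labels.tsv")
    outputs["labels"] = outdir / "labels.tsv"

    config_entries: dict[str, object] = {
        "groups": "groups.txt",
        "labels": "labels.tsv",
        "seed": truth.seed,
        "output_dir": "reports",
    }

    if truth.consensus:
        aln = generate_alignment(
            truth.consensus, len(truth.genome_ids), truth.mutation_rate,
            seed=truth.seed,
        )
        aln = type(aln)(tuple(
            (strain, seq)
            for strain, (_, seq) in zip(truth.genome_ids, aln.records)
        ))
        write_alignment(aln, outdir / "alignment.fasta")
        outputs["alignment"] = outdir / "alignment.fasta"
        config_entries["alignment"] = "alignment.fasta"

    if truth.trait_prevalences:
        traits = generate_traits(truth)
        write_matrix(traits, outdir / "traits.tsv")
        outputs["traits"] = outdir / "traits.tsv"
        config_entries["traits"] = "traits.tsv"

    if truth.class_specs:
        util, classes, _ = generate_utilization(truth)
        write_matrix(util, outdir / "utilization.tsv")
        write_compound_classes(classes, outdir / "compound_classes.tsv")
        outputs["utilization"] = outdir / "utilization.tsv"
        outputs["compound_classes"] = outdir / "compound_classes.tsv"
        config_entries["utilization"] = "utilization.tsv"
        config_entries["compound_classes"] = "compound_classes.tsv"
        pred = generate_predictions(util, truth.prediction_error_rate,
                                    seed=truth.seed)
        write_matrix(pred, outdir / "predictions.tsv")
        outputs["predictions"] = outdir / "predictions.tsv"
        config_entries["predictions"] = "predictions.tsv"

    if reactions:
        rxn = plant_reaction_matrix(
            labels,
            core=int(reactions["core"]),
            shared_non_core=int(reactions["shared_non_core"]),
            rhizosphere_only=int(reactions["rhizosphere_only"]),
            endosphere_only=int(reactions["endosphere_only"]),
            seed=truth.seed,
        )
        write_matrix(rxn, outdir / "reactions.tsv")
        outputs["reactions"] = outdir / "reactions.tsv"
        config_entries["reactions"] = "reactions.tsv"

    with open(outdir / "config.yaml", "wt", encoding="utf-8") as fh:
        yaml.safe_dump(config_entries, fh, sort_keys=True)
    outputs["config"] = outdir / "config.yaml"

    truth_dict = dataclasses.asdict(truth)
    truth_dict["venn_counts"] = (
        {f"{r}/{e}": v for (r, e), v in truth.venn_counts.items()}
        if truth.venn_counts else None
    )
    truth_dict["class_specs"] = [dataclasses.asdict(c) for c in truth.class_specs]
    truth_dict["trait_prevalences"] = {
        k: list(v) for k, v in truth.trait_prevalences.items()
    }
    truth_dict["reactions"] = reactions
    with open(outdir / "truth.json", "wt", encoding="utf-8") as fh:
        json.dump(truth_dict, fh, indent=2, sort_keys=True)
        fh.write("\n")
    outputs["truth"] = outdir / "truth.json"
    return outputs
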