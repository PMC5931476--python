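"""End-to-end orchestration: burn-in through classification and reports.

The stage order follows the analysis the package implements: discard
burn-in from each genome's MCMC tree sample, reduce both to the shared
species set, summarise each genome as a 50% majority-rule consensus with
posterior supports, pool the two populations with equal weight into a
combined consensus annotated with internode certainty, detect supported
conflicts per species, classify them (ILS vs hybridisation candidates) and
export a tanglegram bundle.  All defaults equal the study settings:
burn-in fraction 0.25, consensus threshold 0.5, PP threshold 0.95, ILD
with 100 replicates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

from . import consensus as cns
from . import incongruence as inc
from . import parsimony as pars
from .treeio import TreeSampleSet, apply_burnin, read_tree_samples, write_newick

__all__ = [
    "PipelineConfig",
    "run_incongruence_pipeline",
    "run_ild",
    "run_simulation_study",
]


@dataclass
class PipelineConfig:
    """All knobs of the incongruence pipeline, defaulting to the study settings."""

    samples_a: str | None = None          # chloroplast tree samples
    samples_b: str | None = None          # nuclear tree samples
    taxon_map: str | None = None
    alignment_a: str | None = None
    alignment_b: str | None = None
    genome_a: str = "cpDNA"
    genome_b: str = "nrITS"
    burnin_fraction: float = 0.25
    consensus_threshold: float = 0.5
    pp_threshold: float = 0.95
    pooling_weights: tuple[float, float] = (0.5, 0.5)
    ild_replicates: int = 100
    exclusions_a: str = ""
    exclusions_b: str = ""
    seed: int = 0
    output_dir: str = "."


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()[:16]


def _load_taxon_rows(path: str) -> list[tuple[str, str, str]]:
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or (i == 0 and line.lower().startswith("accession")):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"taxon map line {i + 1} is not a 3-column row")
            rows.append((parts[0], parts[1], parts[2]))
    return rows


def run_incongruence_pipeline(
    config: PipelineConfig,
    samples_a: TreeSampleSet | None = None,
    samples_b: TreeSampleSet | None = None,
    taxon_rows: list[tuple[str, str, str]] | None = None,
    write_outputs: bool = True,
) -> dict:
    """Run burn-in -> consensus -> pooled IC -> classification -> tanglegram.

    Inputs may be passed in memory (scenario objects) or read from the
    configured paths.  Returns the report bundle as a dict; with
    ``write_outputs`` the TSV/JSON/Newick artefacts and a parameter log are
    written under ``config.output_dir``.
    """
    log: dict = {"stages": [], "config": dataclasses.asdict(config)}

    def stage(name: str, **info) -> None:
        log["stages"].append({"stage": name, **info})

    try:
        if samples_a is None:
            samples_a = read_tree_samples(config.samples_a,
                                          genome_tag=config.genome_a)
            stage("read_samples_a", path=config.samples_a,
                  digest=_digest(config.samples_a), n=len(samples_a))
        if samples_b is None:
            samples_b = read_tree_samples(config.samples_b,
                                          genome_tag=config.genome_b)
            stage("read_samples_b", path=config.samples_b,
                  digest=_digest(config.samples_b), n=len(samples_b))
        if taxon_rows is None and config.taxon_map:
            taxon_rows = _load_taxon_rows(config.taxon_map)
    except Exception as exc:
        raise RuntimeError(f"stage input-loading failed: {exc}") from exc

    if not samples_a.burnin_applied:
        samples_a = apply_burnin(samples_a, config.burnin_fraction)
    if not samples_b.burnin_applied:
        samples_b = apply_burnin(samples_b, config.burnin_fraction)
    stage("burnin", fraction=config.burnin_fraction,
          retained_a=len(samples_a), retained_b=len(samples_b))

    tmap = None
    if taxon_rows:
        tmap = inc.build_taxon_map(taxon_rows, samples_a.leaf_labels(),
                                   samples_b.leaf_labels(),
                                   genome_a=config.genome_a,
                                   genome_b=config.genome_b)
    shared_labels = samples_a.leaf_labels() & samples_b.leaf_labels()
    if len(shared_labels) < 4:
        raise RuntimeError("stage prune-to-shared failed: fewer than 4 shared labels")
    pruned_a = samples_a.prune_to(shared_labels)
    pruned_b = samples_b.prune_to(shared_labels)
    stage("prune_to_shared", n_shared=len(shared_labels))

    table_a = cns.bipartition_frequencies([pruned_a])
    table_b = cns.bipartition_frequencies([pruned_b])
    cons_a = cns.majority_rule_consensus(table_a, config.consensus_threshold)
    cons_b = cns.majority_rule_consensus(table_b, config.consensus_threshold)
    stage("per_genome_consensus", threshold=config.consensus_threshold)

    pooled = cns.bipartition_frequencies([pruned_a, pruned_b],
                                         weights=list(config.pooling_weights))
    combined = cns.majority_rule_consensus(pooled, config.consensus_threshold)
    combined = cns.annotate_consensus_with_ic(combined, pooled)
    stage("pooled_consensus_ic", weights=list(config.pooling_weights))

    calls = inc.classify_species(cons_a, cons_b, taxon_map=tmap,
                                 pp_threshold=config.pp_threshold,
                                 genome_a=config.genome_a,
                                 genome_b=config.genome_b)
    summary = inc.summarise_calls(calls)
    stage("classification", pp_threshold=config.pp_threshold,
          counts=summary["category_counts"])

    if tmap is not None:
        tgm_a, tgm_b = inc.collapse_accession_pair(
            cons_a, cons_b, tmap, config.genome_a, config.genome_b)
    else:
        tgm_a, tgm_b = cons_a, cons_b
    shared_sp = sorted(tgm_a.leaf_labels() & tgm_b.leaf_labels())
    tangle = inc.tanglegram_export(
        tgm_a.prune_to(shared_sp), tgm_b.prune_to(shared_sp),
        calls=calls, pp_threshold=config.pp_threshold, seed=config.seed)
    stage("tanglegram", crossings=tangle["crossings"])

    report = {
        "calls": calls,
        "summary": summary,
        "consensus_a": cons_a,
        "consensus_b": cons_b,
        "combined_consensus": combined,
        "pooled_table": pooled,
        "tanglegram": tangle,
        "log": log,
    }
    if write_outputs:
        outdir = config.output_dir
        os.makedirs(outdir, exist_ok=True)

        def put(name: str, text: str) -> None:
            with open(os.path.join(outdir, name), "w") as fh:
                fh.write(text)

        put("calls.tsv", inc.calls_tsv(calls))
        put("summary.json", json.dumps(summary, indent=2, sort_keys=True) + "\n")
        put("consensus_a.nwk", write_newick(cons_a, include_lengths=False) + "\n")
        put("consensus_b.nwk", write_newick(cons_b, include_lengths=False) + "\n")
        put("combined_ic.nwk",
            write_newick(combined, include_lengths=False, include_ic=True) + "\n")
        put("pooled_frequencies.tsv", cns.frequency_table_tsv(pooled))
        put("tanglegram_a.nwk", tangle["newick_a"] + "\n")
        put("tanglegram_b.nwk", tangle["newick_b"] + "\n")
        put("tanglegram_links.tsv", tangle["links_tsv"])
        put("pipeline_log.json", json.dumps(log, indent=2, sort_keys=True) + "\n")
    return report


def run_ild(config: PipelineConfig,
            aln_a: "pars.Alignment | None" = None,
            aln_b: "pars.Alignment | None" = None,
            write_outputs: bool = True) -> pars.ILDResult:
    """Run the ILD test stage with the configured replicate count and seed."""
    if aln_a is None:
        aln_a = pars.read_alignment_file(config.alignment_a)
    if aln_b is None:
        aln_b = pars.read_alignment_file(config.alignment_b)
    if config.exclusions_a:
        aln_a = pars.apply_exclusion_ranges(
            aln_a, pars.parse_exclusion_spec(config.exclusions_a))
    if config.exclusions_b:
        aln_b = pars.apply_exclusion_ranges(
            aln_b, pars.parse_exclusion_spec(config.exclusions_b))
    result = pars.ild_test(aln_a, aln_b, replicates=config.ild_replicates,
                           seed=config.seed)
    if write_outputs:
        os.makedirs(config.output_dir, exist_ok=True)
        with open(os.path.join(config.output_dir, "ild_report.json"), "w") as fh:
            fh.write(result.to_json() + "\n")
        with open(os.path.join(config.output_dir, "ild_replicates.tsv"), "w") as fh:
            fh.write(result.replicates_tsv())
    return result


def run_simulation_study(
    perturb_rates: tuple[float, ...] = (0.0, 0.02, 0.05),
    n_replicates: int = 10,
    scenario_kwargs: dict | None = None,
    seed: int = 0,
    pp_threshold: float = 0.95,
):
    """Recovery metrics over a grid of perturbation rates.

    For each grid cell (rate, replicate) a scenario is generated, the
    pipeline's consensus + classification stages are run, and the cell
    records the capture-recovery rate, the false-positive rate among
    unmanipulated species, and the mean internode certainty at implanted
    versus undisturbed edges of the pooled consensus.  Returns a pandas
    DataFrame, one row per cell.
    """
    import pandas as pd

    from .simulate import ScenarioConfig, generate_scenario

    scenario_kwargs = dict(scenario_kwargs or {})
    rows = []
    for rate in perturb_rates:
        for rep in range(n_replicates):
            cfg = ScenarioConfig(perturb_rate=rate,
                                 seed=seed + 1000 * rep + int(rate * 100000) % 997,
                                 **scenario_kwargs)
            scenario = generate_scenario(cfg)
            metrics = evaluate_scenario(scenario, pp_threshold=pp_threshold)
            rows.append({"perturb_rate": rate, "replicate": rep, **metrics})
    return pd.DataFrame(rows)


def evaluate_scenario(scenario, pp_threshold: float = 0.95) -> dict:
    """Classify one scenario against its truth table.

    Returns recovery (implanted events called with the expected category),
    hybridisation recovery (displacement >= 2 events called hybridisation
    candidates), false-positive rate among unmanipulated species, and mean
    IC at implanted vs undisturbed base-tree edges.
    """
    from .incongruence import HYBRIDISATION_CANDIDATE

    table_a = cns.bipartition_frequencies([scenario.samples_plastid])
    table_b = cns.bipartition_frequencies([scenario.samples_nuclear])
    cons_a = cns.majority_rule_consensus(table_a)
    cons_b = cns.majority_rule_consensus(table_b)
    tmap = inc.build_taxon_map(scenario.taxon_rows,
                               scenario.samples_plastid.leaf_labels(),
                               scenario.samples_nuclear.leaf_labels())
    calls = inc.classify_species(cons_a, cons_b, taxon_map=tmap,
                                 pp_threshold=pp_threshold)
    by_species = {c.species: c for c in calls}
    truth = {s: (d, cat) for s, d, cat in scenario.truth_rows()}

    n_events = len(truth)
    recovered = sum(
        1 for s, (d, cat) in truth.items()
        if s in by_species and by_species[s].category == cat)
    hyb_truth = [s for s, (d, _) in truth.items() if d >= 2]
    hyb_recovered = sum(
        1 for s in hyb_truth
        if s in by_species and by_species[s].category == HYBRIDISATION_CANDIDATE)
    untouched = [s for s in by_species if s not in truth]
    false_pos = sum(1 for s in untouched if by_species[s].supported_conflict)

    pooled = cns.bipartition_frequencies(
        [scenario.samples_plastid.prune_to(scenario.samples_nuclear.leaf_labels()),
         scenario.samples_nuclear])
    base_splits = cns.bipartition_set(scenario.base_tree)
    derived_splits = cns.bipartition_set(scenario.derived_tree)
    disturbed = base_splits - derived_splits
    undisturbed = base_splits & derived_splits
    ic_disturbed = [cns.internode_certainty(pooled, b) for b in disturbed
                    if pooled.frequency(b) > 0]
    ic_undisturbed = [cns.internode_certainty(pooled, b) for b in undisturbed
                      if pooled.frequency(b) > 0]
    return {
        "n_events": n_events,
        "recovery": recovered / n_events if n_events else 1.0,
        "hyb_recovery": (hyb_recovered / len(hyb_truth)) if hyb_truth else 1.0,
        "false_positive_rate": false_pos / len(untouched) if untouched else 0.0,
        "mean_ic_disturbed": (sum(ic_disturbed) / len(ic_disturbed)
                              if ic_disturbed else float("nan")),
        "mean_ic_undisturbed": (sum(ic_undisturbed) / len(ic_undisturbed)
                                if ic_undisturbed else float("nan")),
    }
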