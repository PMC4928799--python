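"""End-to-end orchestration: ingest → map → count → test → compare → report.

A run is driven by one YAML config and produces a deterministic bundle of
TSV tables plus a JSON manifest in the output directory:

    mapability.tsv            per-set ID-mapping report
    count_histogram.tsv       normalized ortholog-count distribution
    set_statistics.tsv        per-set totals/means/SDs with resampling p-values
    per_species_pvalues.tsv   set x species enrichment p-values (raw)
    per_species_pvalues_bh.tsv   the same, BH-adjusted within each set
    ks_summary.tsv / ks_curves.tsv / boxplot_summary.tsv   clade comparisons
    subset_*.tsv              clade-conserved subsets with up/down partition
    terms_*.tsv               term over-representation per direction context
    manifest.json             inputs, seed, resample count, package version

The bundle is assembled in a temporary directory and moved into place
atomically; any stage error aborts the run with the stage name and leaves
no partial outputs.
"""

from __future__ import annotations

import csv
import json
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import __version__
from .annotation_enrichment import term_overrepresentation
from .conservation import (
    clade_conserved_subset,
    count_distribution,
    ortholog_count_per_gene,
    partition_by_direction,
    per_species_set_counts,
    set_statistics,
)
from .datatypes import GeneSet, ValidationError
from .distribution_stats import clade_comparison, ks_two_sample
from .io_formats import (
    fmt,
    map_ids,
    read_annotation,
    read_gene_sets,
    read_id_map,
    read_ortholog_table,
    read_species_panel,
    write_gene_sets,
    write_ks_summary,
    write_per_species_pvalues,
    write_set_statistics,
    write_term_enrichment,
)
from .resampling import bh_adjust, permutation_test_mean, permutation_test_per_species

__all__ = ["RunConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    panel: Path
    ortholog_table: Path
    gene_sets: Path
    out_dir: Path
    dialect: str = "presence-matrix-tsv"
    id_map: Optional[Path] = None
    term_map: Optional[Path] = None
    term_parents: Optional[Path] = None
    n_resamples: int = 10_000
    seed: int = 0
    exact_threshold: int = 20_000
    conserved_clades: tuple[str, ...] = ()
    # each entry: (set_name, clade_a, clade_b)
    clade_comparisons: tuple[tuple[str, str, str], ...] = ()
    # each entry: (set_a, set_b) -- KS between the sets' per-species p vectors
    set_comparisons: tuple[tuple[str, str], ...] = ()
    term_method: str = "hypergeometric"
    term_background: str = "annotated"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent

        def p(key, required=False):
            v = raw.get(key)
            if v is None:
                if required:
                    raise ValidationError(f"config missing required key {key!r}")
                return None
            q = Path(v)
            return q if q.is_absolute() else base / q

        cfg = cls(
            panel=p("panel", required=True),
            ortholog_table=p("ortholog_table", required=True),
            gene_sets=p("gene_sets", required=True),
            out_dir=p("out_dir", required=True),
            dialect=raw.get("dialect", "presence-matrix-tsv"),
            id_map=p("id_map"),
            term_map=p("term_map"),
            term_parents=p("term_parents"),
            n_resamples=int(raw.get("n_resamples", 10_000)),
            seed=int(raw.get("seed", 0)),
            exact_threshold=int(raw.get("exact_threshold", 20_000)),
            conserved_clades=tuple(raw.get("conserved_clades", ())),
            clade_comparisons=tuple(
                (c["set"], c["clade_a"], c["clade_b"])
                for c in raw.get("clade_comparisons", ())
            ),
            set_comparisons=tuple(
                (c["set_a"], c["set_b"]) for c in raw.get("set_comparisons", ())
            ),
            term_method=raw.get("term_method", "hypergeometric"),
            term_background=raw.get("term_background", "annotated"),
        )
        for key in ("panel", "ortholog_table", "gene_sets", "id_map", "term_map", "term_parents"):
            v = getattr(cfg, key)
            if v is not None and not Path(v).exists():
                raise ValidationError(f"config {key}: file {v} does not exist")
        return cfg


def _write_curves(rows, path):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["comparison", "value", "cum_frac_a", "cum_frac_b"])
        for comp, ks in rows:
            for v, f1, f2 in zip(ks.curve_values, ks.curve_f1, ks.curve_f2):
                w.writerow([comp, fmt(v), fmt(f1), fmt(f2)])


def _write_boxplots(rows, path):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["comparison", "group", "min", "q1", "median", "q3", "max"])
        for comp, group, s in rows:
            w.writerow([comp, group, *(fmt(s[k]) for k in ("min", "q1", "median", "q3", "max"))])


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the output bundle directory."""
    out_dir = Path(config.out_dir)
    out_dir.parent.mkdir(parents=True, exist_ok=True)
    tmp = Path(tempfile.mkdtemp(prefix=".orthoconserve_", dir=out_dir.parent))
    try:
        _run_stages(config, tmp)
        if out_dir.exists():
            shutil.rmtree(out_dir)
        tmp.replace(out_dir)
    except StageError:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    except Exception as exc:  # pragma: no cover - defensive
        shutil.rmtree(tmp, ignore_errors=True)
        raise StageError("unknown", exc) from exc
    return out_dir


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return wrapper
    return deco


def _run_stages(config: RunConfig, out: Path) -> None:
    panel, matrix, raw_sets = _ingest(config)
    mapped_sets = _map_stage(config, out, panel, matrix, raw_sets)
    _counts_stage(config, out, matrix, mapped_sets)
    pvals = _enrich_stage(config, out, panel, matrix, mapped_sets)
    _compare_stage(config, out, panel, pvals)
    subsets = _subset_stage(config, out, panel, matrix, mapped_sets)
    _terms_stage(config, out, matrix, subsets)
    _manifest(config, out)


@_stage("ingest")
def _ingest(config: RunConfig):
    panel = read_species_panel(config.panel)
    matrix = read_ortholog_table(config.ortholog_table, config.dialect, panel)
    gene_sets = read_gene_sets(config.gene_sets)
    return panel, matrix, gene_sets


@_stage("map-ids")
def _map_stage(config, out, panel, matrix, raw_sets) -> list[GeneSet]:
    if config.id_map is not None:
        id_map = read_id_map(config.id_map)
        mapped, reports = [], []
        for gs in raw_sets:
            m, rep = map_ids(gs, id_map, matrix)
            mapped.append(m)
            reports.append(rep)
    else:
        mapped = []
        reports = []
        for gs in raw_sets:
            kept = tuple(g for g in gs.genes if g in matrix)
            dirs = gs.direction_of
            mapped.append(
                GeneSet(gs.name, kept,
                        {g: dirs[g] for g in kept if g in dirs} if dirs else None,
                        gs.description)
            )
            reports.append(None)
    with open(out / "mapability.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["set", "n_input", "n_mapable", "n_dropped_unmapped", "n_dropped_absent"])
        for gs, m, rep in zip(raw_sets, mapped, reports):
            if rep is None:
                w.writerow([gs.name, len(gs.genes), len(m.genes),
                            0, len(gs.genes) - len(m.genes)])
            else:
                w.writerow([gs.name, rep.n_input, rep.n_mapped,
                            rep.n_dropped_unmapped, rep.n_dropped_absent])
    empty = [m.name for m in mapped if len(m.genes) == 0]
    if empty:
        raise ValidationError(f"set {empty[0]!r} has no mapable genes")
    return mapped


@_stage("counts")
def _counts_stage(config, out, matrix, mapped_sets) -> None:
    counts = ortholog_count_per_gene(matrix)
    dist = count_distribution(counts, matrix.n_species)
    with open(out / "count_histogram.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["n_orthologs", "fraction"])
        for k, frac in enumerate(dist):
            w.writerow([k, fmt(frac)])


@_stage("enrich")
def _enrich_stage(config, out, panel, matrix, mapped_sets):
    stat_rows = []
    raw_p: dict[str, dict[str, float]] = {}
    bh_p: dict[str, dict[str, float]] = {}
    for gs in mapped_sets:
        stats_ = set_statistics(matrix, gs)
        res = permutation_test_mean(
            matrix, gs, n_resamples=config.n_resamples,
            seed=config.seed, exact_threshold=config.exact_threshold,
        )
        row = dict(stats_)
        row["p_enrich"] = res.p_enrich
        row["p_deplete"] = res.p_deplete
        stat_rows.append(row)
        per_sp = permutation_test_per_species(
            matrix, gs, n_resamples=config.n_resamples,
            seed=config.seed, exact_threshold=config.exact_threshold,
        )
        col = {r.species: r.p_enrich for r in per_sp}
        raw_p[gs.name] = {s: col[s] for s in matrix.species}
        adj = bh_adjust([col[s] for s in matrix.species])
        bh_p[gs.name] = dict(zip(matrix.species, adj.tolist()))
    names = [r["set"] for r in stat_rows]
    for key in ("p_enrich", "p_deplete"):
        adj = bh_adjust([r[key] for r in stat_rows])
        for r, v in zip(stat_rows, adj):
            r[f"{key}_bh"] = float(v)
    write_set_statistics(stat_rows, out / "set_statistics.tsv")
    write_per_species_pvalues(raw_p, panel, out / "per_species_pvalues.tsv")
    write_per_species_pvalues(bh_p, panel, out / "per_species_pvalues_bh.tsv")
    return raw_p


@_stage("compare")
def _compare_stage(config, out, panel, pvals) -> None:
    ks_rows, curve_rows, box_rows = [], [], []
    for set_name, clade_a, clade_b in config.clade_comparisons:
        if set_name not in pvals:
            raise ValidationError(f"clade comparison references unknown set {set_name!r}")
        summaries, ks = clade_comparison(pvals[set_name], panel, clade_a, clade_b)
        comp = f"{set_name}:{clade_a}-vs-{clade_b}"
        ks_rows.append({"comparison": comp, "n1": ks.n1, "n2": ks.n2,
                        "D": ks.D, "P": ks.P, "lambda": ks.lam})
        curve_rows.append((comp, ks))
        box_rows.append((comp, clade_a, summaries[clade_a]))
        box_rows.append((comp, clade_b, summaries[clade_b]))
    for set_a, set_b in config.set_comparisons:
        for name in (set_a, set_b):
            if name not in pvals:
                raise ValidationError(f"set comparison references unknown set {name!r}")
        va = list(pvals[set_a].values())
        vb = list(pvals[set_b].values())
        ks = ks_two_sample(va, vb)
        comp = f"{set_a}-vs-{set_b}"
        ks_rows.append({"comparison": comp, "n1": ks.n1, "n2": ks.n2,
                        "D": ks.D, "P": ks.P, "lambda": ks.lam})
        curve_rows.append((comp, ks))
    write_ks_summary(ks_rows, out / "ks_summary.tsv")
    _write_curves(curve_rows, out / "ks_curves.tsv")
    _write_boxplots(box_rows, out / "boxplot_summary.tsv")


@_stage("subsets")
def _subset_stage(config, out, panel, matrix, mapped_sets) -> list[GeneSet]:
    subsets: list[GeneSet] = []
    for clade in config.conserved_clades:
        for gs in mapped_sets:
            sub = clade_conserved_subset(matrix, gs, panel, clade)
            emit = [sub]
            if sub.direction_of and len(sub.direction_of) == len(sub.genes) and sub.genes:
                up, down = partition_by_direction(sub)
                emit += [up, down]
            write_gene_sets(emit, out / f"subset_{sub.name}.tsv")
            subsets.append(sub)
    return subsets


@_stage("terms")
def _terms_stage(config, out, matrix, subsets) -> None:
    if config.term_map is None:
        return
    term_map, _ = read_annotation(config.term_map, config.term_parents)
    population = list(matrix.genes)
    for sub in subsets:
        if not sub.genes:
            continue
        contexts = {"combined": sub}
        if sub.direction_of and len(sub.direction_of) == len(sub.genes):
            up, down = partition_by_direction(sub)
            if up.genes:
                contexts["up"] = up
            if down.genes:
                contexts["down"] = down
        for ctx, gs in contexts.items():
            results = term_overrepresentation(
                gs.genes, population, term_map,
                method=config.term_method, background=config.term_background,
                direction_context=ctx,
            )
            write_term_enrichment(results, out / f"terms_{sub.name}_{ctx}.tsv")


@_stage("manifest")
def _manifest(config: RunConfig, out: Path) -> None:
    manifest = {
        "package": "orthoconserve",
        "version": __version__,
        "seed": config.seed,
        "n_resamples": config.n_resamples,
        "exact_threshold": config.exact_threshold,
        "dialect": config.dialect,
        "inputs": {
            k: (str(getattr(config, k)) if getattr(config, k) is not None else None)
            for k in ("panel", "ortholog_table", "gene_sets", "id_map", "term_map", "term_parents")
        },
        "conserved_clades": list(config.conserved_clades),
        "clade_comparisons": [list(c) for c in config.clade_comparisons],
        "set_comparisons": [list(c) for c in config.set_comparisons],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
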