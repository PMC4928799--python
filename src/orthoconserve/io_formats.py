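"""Readers and writers for every table the pipeline touches.

All logic consumes plain TSV; a thin XLSX adapter converts supplementary
spreadsheets to the same dialects. Three ortholog-table dialects are
supported:

* ``simple-tsv``    — one row per (gene_id, species_id) presence call
* ``cluster-tsv``   — one row per (cluster_id, species_id, gene_id) cluster
  member, as exported from InParanoid/OrthoMCL-style cluster tables; the
  reference species' members name the genes
* ``presence-matrix-tsv`` — genes x species 0/1 matrix

Multiple orthologs of one gene in one species collapse to presence = 1.
ID mapping is many-to-one (platform ID → ortholog-database ID); ambiguous
sources are rejected at parse time with a logged count.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .datatypes import (
    GeneSet,
    IdMap,
    OrthologMatrix,
    SpeciesPanel,
    ValidationError,
)

__all__ = [
    "MapReport",
    "read_ortholog_table",
    "write_ortholog_table",
    "map_ids",
    "read_gene_sets",
    "write_gene_sets",
    "read_species_panel",
    "write_species_panel",
    "read_id_map",
    "write_id_map",
    "read_annotation",
    "write_annotation",
    "write_set_statistics",
    "write_per_species_pvalues",
    "write_ks_summary",
    "write_term_enrichment",
    "xlsx_to_tsv",
    "fmt",
]

logger = logging.getLogger(__name__)

DIALECTS = ("simple-tsv", "cluster-tsv", "presence-matrix-tsv")


def fmt(x: float) -> str:
    """Fixed 6-significant-digit float formatting for deterministic output."""
    return format(float(x), ".6g")


def _rows(path: Path, expected_cols: int, what: str) -> Iterable[tuple[int, list[str]]]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != expected_cols:
                raise ValidationError(
                    f"{what}: line {lineno} of {path} has {len(row)} columns, expected {expected_cols}"
                )
            yield lineno, row


# ---------------------------------------------------------------------------
# ortholog tables


def read_ortholog_table(path, dialect: str, panel: SpeciesPanel) -> OrthologMatrix:
    """Parse an ortholog table into a presence matrix over the panel's species.

    A species appearing in the file but absent from the panel is an error;
    rows for the reference species (cluster-tsv) name the genes.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if dialect == "presence-matrix-tsv":
        return _read_presence_matrix(path, panel)
    counting = set(panel.species)
    presence_pairs: dict[str, set[str]] = {}
    if dialect == "simple-tsv":
        rows = _rows(path, 2, "simple-tsv")
        header_seen = False
        for lineno, row in rows:
            if not header_seen:
                header_seen = True
                if row[0].lower() in ("gene_id", "gene"):
                    continue
            gene, sp = row
            if sp == panel.reference_species:
                continue
            if sp not in counting:
                raise ValidationError(f"line {lineno}: species {sp!r} not in panel")
            presence_pairs.setdefault(gene, set()).add(sp)
    else:  # cluster-tsv
        clusters: dict[str, tuple[set[str], set[str]]] = {}  # id -> (ref genes, species)
        header_seen = False
        for lineno, row in _rows(path, 3, "cluster-tsv"):
            if not header_seen:
                header_seen = True
                if row[0].lower() in ("cluster_id", "cluster"):
                    continue
            cluster, sp, gene = row
            ref_genes, species_hit = clusters.setdefault(cluster, (set(), set()))
            if sp == panel.reference_species:
                ref_genes.add(gene)
            elif sp in counting:
                species_hit.add(sp)
            else:
                raise ValidationError(f"line {lineno}: species {sp!r} not in panel")
        for ref_genes, species_hit in clusters.values():
            for gene in ref_genes:
                presence_pairs.setdefault(gene, set()).update(species_hit)
    if not presence_pairs:
        raise ValidationError(f"{path}: empty ortholog table")
    genes = tuple(sorted(presence_pairs))
    pres = np.zeros((len(genes), len(panel.species)), dtype=bool)
    col = {s: j for j, s in enumerate(panel.species)}
    for i, g in enumerate(genes):
        for sp in presence_pairs[g]:
            pres[i, col[sp]] = True
    return OrthologMatrix(genes, panel.species, pres)


def _read_presence_matrix(path: Path, panel: SpeciesPanel) -> OrthologMatrix:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty ortholog table") from None
        file_species = header[1:]
        unknown = [s for s in file_species if s not in set(panel.species)]
        if unknown:
            raise ValidationError(f"species {unknown[0]!r} not in panel")
        genes: list[str] = []
        rows: list[list[bool]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ValidationError(
                    f"presence-matrix-tsv: line {lineno} has {len(row)} columns, expected {len(header)}"
                )
            genes.append(row[0])
            rows.append([c.strip() in ("1", "True", "true") for c in row[1:]])
    if not genes:
        raise ValidationError(f"{path}: empty ortholog table")
    # re-order columns to panel order; species missing from the file are absent
    pres = np.zeros((len(genes), len(panel.species)), dtype=bool)
    file_col = {s: j for j, s in enumerate(file_species)}
    data = np.asarray(rows, dtype=bool)
    for j, s in enumerate(panel.species):
        if s in file_col:
            pres[:, j] = data[:, file_col[s]]
    return OrthologMatrix(tuple(genes), panel.species, pres)


def write_ortholog_table(matrix: OrthologMatrix, path) -> None:
    """Write the presence-matrix-tsv dialect (round-trips with the reader)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", *matrix.species])
        for i, g in enumerate(matrix.genes):
            w.writerow([g, *("1" if v else "0" for v in matrix.presence[i])])


# ---------------------------------------------------------------------------
# ID mapping


@dataclass(frozen=True)
class MapReport:
    """Mapability accounting for one gene set (counts sum to n_input)."""

    set_name: str
    n_input: int
    n_mapped: int
    n_dropped_unmapped: int
    n_dropped_absent: int

    def __post_init__(self) -> None:
        assert self.n_mapped + self.n_dropped_unmapped + self.n_dropped_absent == self.n_input


def map_ids(gene_set: GeneSet, id_map: IdMap, matrix: OrthologMatrix) -> tuple[GeneSet, MapReport]:
    """Map a set's platform IDs into the matrix's gene universe.

    Retains genes whose mapped ID is a matrix row; two sources hitting one
    target collapse to a single output gene (both count as mapped).
    Direction labels follow the genes through the mapping.
    """
    mapped_genes: list[str] = []
    seen_targets: set[str] = set()
    directions: dict[str, str] = {}
    n_mapped = n_unmapped = n_absent = 0
    src_dirs = gene_set.direction_of or {}
    for g in gene_set.genes:
        target = id_map.get(g)
        if target is None:
            n_unmapped += 1
            continue
        if target not in matrix:
            n_absent += 1
            continue
        n_mapped += 1
        if target not in seen_targets:
            seen_targets.add(target)
            mapped_genes.append(target)
            if g in src_dirs:
                directions[target] = src_dirs[g]
    report = MapReport(gene_set.name, len(gene_set.genes), n_mapped, n_unmapped, n_absent)
    logger.info(
        "map_ids %s: %d input, %d mapped, %d unmapped, %d absent from matrix",
        gene_set.name, report.n_input, n_mapped, n_unmapped, n_absent,
    )
    out = GeneSet(
        name=gene_set.name,
        genes=tuple(mapped_genes),
        direction_of=directions if src_dirs else None,
        description=gene_set.description,
    )
    return out, report


def read_id_map(path) -> IdMap:
    """Two-column TSV (source, target); ambiguous sources are dropped with a logged count."""
    targets: dict[str, set[str]] = {}
    header_seen = False
    for lineno, row in _rows(Path(path), 2, "id-map"):
        if not header_seen:
            header_seen = True
            if row[0].lower() in ("source", "source_id", "platform_id"):
                continue
        targets.setdefault(row[0], set()).add(row[1])
    ambiguous = {s for s, t in targets.items() if len(t) > 1}
    if ambiguous:
        logger.warning("id map: dropped %d ambiguous source IDs", len(ambiguous))
    pairs = {s: next(iter(t)) for s, t in targets.items() if len(t) == 1}
    return IdMap(pairs, n_ambiguous_dropped=len(ambiguous))


def write_id_map(id_map: IdMap, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["source", "target"])
        for s in sorted(id_map.pairs):
            w.writerow([s, id_map.pairs[s]])


# ---------------------------------------------------------------------------
# gene sets, panels, annotations


def read_gene_sets(path) -> list[GeneSet]:
    """TSV with header (set, gene[, direction]); direction values in {up, down}."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty gene-set file") from None
        has_dir = len(header) >= 3
        order: list[str] = []
        genes: dict[str, list[str]] = {}
        dirs: dict[str, dict[str, str]] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise ValidationError(
                    f"gene-set file: line {lineno} has {len(row)} columns, expected {len(header)}"
                )
            name, gene = row[0], row[1]
            if name not in genes:
                genes[name] = []
                dirs[name] = {}
                order.append(name)
            if gene in set(genes[name]):
                raise ValidationError(f"line {lineno}: duplicate gene {gene!r} in set {name!r}")
            genes[name].append(gene)
            if has_dir and row[2].strip():
                d = row[2].strip().lower()
                if d not in ("up", "down"):
                    raise ValidationError(f"line {lineno}: invalid direction {row[2]!r}")
                dirs[name][gene] = d
    return [
        GeneSet(name, tuple(genes[name]), direction_of=dirs[name] or None)
        for name in order
    ]


def write_gene_sets(gene_sets: Sequence[GeneSet], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["set", "gene", "direction"])
        for gs in gene_sets:
            dirs = gs.direction_of or {}
            for g in gs.genes:
                w.writerow([gs.name, g, dirs.get(g, "")])


def read_species_panel(path) -> SpeciesPanel:
    """TSV with header (species, clade, is_reference); file order is display order."""
    path = Path(path)
    species: list[str] = []
    clade_of: dict[str, str] = {}
    reference: Optional[str] = None
    header_seen = False
    for lineno, row in _rows(path, 3, "species-panel"):
        if not header_seen:
            header_seen = True
            if row[0].lower() == "species":
                continue
        sp, clade, is_ref = row[0], row[1].strip(), row[2].strip()
        if is_ref in ("1", "true", "True"):
            reference = sp
            continue
        if not clade:
            raise ValidationError(f"line {lineno}: species {sp!r} has no clade label")
        species.append(sp)
        clade_of[sp] = clade
    return SpeciesPanel(tuple(species), clade_of, reference_species=reference or "reference")


def write_species_panel(panel: SpeciesPanel, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["species", "clade", "is_reference"])
        w.writerow([panel.reference_species, "", "1"])
        for s in panel.species:
            w.writerow([s, panel.clade_of[s], "0"])


def read_annotation(term_map_path, parent_path=None):
    """Two-column term map TSV (term_id, gene_id) plus optional parent TSV (child, parent).

    Returns (term_map: dict term -> tuple of genes, edges: tuple of
    (child, parent)); the parent table must be acyclic.
    """
    term_map: dict[str, list[str]] = {}
    header_seen = False
    for lineno, row in _rows(Path(term_map_path), 2, "term-map"):
        if not header_seen:
            header_seen = True
            if row[0].lower() in ("term", "term_id"):
                continue
        term_map.setdefault(row[0], []).append(row[1])
    edges: list[tuple[str, str]] = []
    if parent_path is not None:
        header_seen = False
        for lineno, row in _rows(Path(parent_path), 2, "term-parents"):
            if not header_seen:
                header_seen = True
                if row[0].lower() in ("child", "child_id"):
                    continue
            edges.append((row[0], row[1]))
        import networkx as nx

        g = nx.DiGraph()
        g.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValidationError("cycle detected in term parent table")
    return {t: tuple(gs) for t, gs in term_map.items()}, tuple(edges)


def write_annotation(term_map: Mapping[str, Sequence[str]], edges, term_map_path, parent_path) -> None:
    with open(term_map_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["term_id", "gene_id"])
        for t in sorted(term_map):
            for g in term_map[t]:
                w.writerow([t, g])
    with open(parent_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["child", "parent"])
        for child, parent in edges:
            w.writerow([child, parent])


# ---------------------------------------------------------------------------
# result writers (deterministic column order, 6 significant digits)


def write_set_statistics(rows: Sequence[Mapping], path) -> None:
    """Set-level statistics table: set, total_orthologs, p_enrich, set_size, mean, sd.

    Extra keys (p_deplete, p_enrich_bh, ...) are appended in sorted order.
    """
    base = ["set", "total_orthologs", "p_enrich", "set_size", "mean", "sd"]
    extra = sorted({k for r in rows for k in r} - set(base))
    cols = base + extra
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(cols)
        for r in rows:
            out = []
            for c in cols:
                v = r.get(c, "")
                out.append(fmt(v) if isinstance(v, float) else v)
            w.writerow(out)


def write_per_species_pvalues(
    pvalues: Mapping[str, Mapping[str, float]], panel: SpeciesPanel, path
) -> None:
    """Set x species p-value matrix in panel display order (heat-map shaped)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["set", *panel.species])
        for set_name in pvalues:
            row = pvalues[set_name]
            w.writerow([set_name, *(fmt(row[s]) for s in panel.species)])


def write_ks_summary(rows: Sequence[Mapping], path) -> None:
    cols = ["comparison", "n1", "n2", "D", "P", "lambda"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(cols)
        for r in rows:
            w.writerow(
                [r["comparison"], r["n1"], r["n2"], fmt(r["D"]), fmt(r["P"]), fmt(r["lambda"])]
            )


def write_term_enrichment(results: Sequence, path) -> None:
    """TermEnrichmentResult rows, ordered by raw p then term id."""
    cols = ["term", "k", "K", "n", "N", "p_raw", "p_bh", "direction_context"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(cols)
        for r in sorted(results, key=lambda r: (r.p_raw, r.term)):
            w.writerow(
                [r.term, r.k, r.K, r.n, r.N, fmt(r.p_raw), fmt(r.p_bh), r.direction_context]
            )


# ---------------------------------------------------------------------------
# XLSX adapter


def xlsx_to_tsv(xlsx_path, tsv_path, sheet: Optional[str] = None) -> None:
    """Convert one worksheet of a supplementary spreadsheet to TSV.

    Thin adapter so spreadsheet supplements can enter the canonical TSV
    code path; all pipeline logic consumes TSV only.
    """
    import openpyxl

    wb = openpyxl.load_workbook(xlsx_path, read_only=True, data_only=True)
    ws = wb[sheet] if sheet else wb.worksheets[0]
    with open(tsv_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for row in ws.iter_rows(values_only=True):
            w.writerow(["" if v is None else v for v in row])
    wb.close()
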