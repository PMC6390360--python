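"""Readers and writers for the pipeline's on-disk formats.

TSV for matrices, manifests and result tables; BED3+name for marker
tracks; GMT for gene-set collections; JSON for truth and run reports.
Coordinates are 0-based half-open throughout.  Readers validate container
invariants on load and report malformed rows with line numbers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneSetCollection
from .containers import BetaMatrix, CohortExpression, ExpressionMatrix, MarkerTrack


class FormatError(ValueError):
    """A file violated its format contract; message carries the location."""


# --- expression / beta matrices -------------------------------------------

def write_matrix_tsv(values: pd.DataFrame, path) -> None:
    values.to_csv(path, sep="\t")


def write_design_tsv(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t")


def _read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("condition", "replicate"):
        if col not in design.columns:
            raise FormatError(f"{path}: design lacks column {col!r}")
    return design


def read_expression_tsv(path, design_path) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    if values.index.duplicated().any():
        dup = values.index[values.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    if (values.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative expression value")
    return ExpressionMatrix(values=values, design=_read_design(design_path))


def read_beta_tsv(path, design_path) -> BetaMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    if values.index.duplicated().any():
        dup = values.index[values.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate probe id {dup!r}")
    arr = values.to_numpy()
    if ((arr < 0) | (arr > 1)).any():
        i, j = np.argwhere((arr < 0) | (arr > 1))[0]
        raise FormatError(
            f"{path}: beta outside [0, 1] at probe {values.index[i]!r}, "
            f"sample {values.columns[j]!r}"
        )
    return BetaMatrix(values=values, design=_read_design(design_path))


# --- probe manifest & gene coordinates ------------------------------------

def write_manifest_tsv(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep="\t")


def read_manifest_tsv(path) -> pd.DataFrame:
    manifest = pd.read_csv(path, sep="\t", index_col=0)
    required = {"chrom", "pos", "cgi_feature", "gene_feature", "gene_id"}
    missing = required - set(manifest.columns)
    if missing:
        raise FormatError(f"{path}: manifest lacks columns {sorted(missing)}")
    if manifest.index.duplicated().any():
        dup = manifest.index[manifest.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate probe id {dup!r}")
    igr = manifest["gene_feature"] == "IGR"
    has_gene = manifest["gene_id"].notna()
    bad = manifest.index[(igr & has_gene) | (~igr & ~has_gene)]
    if len(bad):
        raise FormatError(
            f"{path}: probe {bad[0]!r} violates 'IGR iff no gene' "
            f"(line {manifest.index.get_loc(bad[0]) + 2})"
        )
    return manifest


def write_gene_coords_tsv(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t")


def read_gene_coords_tsv(path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t", index_col=0)
    missing = {"chrom", "tss"} - set(genes.columns)
    if missing:
        raise FormatError(f"{path}: gene table lacks columns {sorted(missing)}")
    return genes


# --- BED marker tracks ------------------------------------------------------

def write_bed(track: MarkerTrack, path) -> None:
    name = f"{track.cell_line}|{track.marker}"
    df = track.intervals.copy()
    df["name"] = name
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, cell_line: str | None = None, marker: str | None = None) -> MarkerTrack:
    """Read a BED3+name track; cell line / marker default to the name field."""
    rows = []
    names = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED fields")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            if len(parts) >= 4:
                names.add(parts[3])
            rows.append((chrom, start, end))
    if cell_line is None or marker is None:
        if len(names) == 1:
            token = names.pop()
            if "|" in token:
                cell_line, marker = token.split("|", 1)
        if cell_line is None or marker is None:
            raise FormatError(f"{path}: cell line / marker not given and not in name field")
    return MarkerTrack(
        cell_line=cell_line,
        marker=marker,
        intervals=pd.DataFrame(rows, columns=["chrom", "start", "end"]),
    )


# --- GMT gene sets ----------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >= 1 member"
                )
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# --- cohort -----------------------------------------------------------------

def write_cohort_tsv(cohort: CohortExpression, path, labels_path) -> None:
    cohort.values.to_csv(path, sep="\t")
    cohort.risk.to_frame().to_csv(labels_path, sep="\t")


def read_cohort(path, labels_path) -> CohortExpression:
    values = pd.read_csv(path, sep="\t", index_col=0)
    labels = pd.read_csv(labels_path, sep="\t", index_col=0)
    if "risk" not in labels.columns:
        raise FormatError(f"{labels_path}: labels need a 'risk' column")
    return CohortExpression(values=values, risk=labels["risk"])


# --- full simulation bundle -------------------------------------------------

def write_simulation(config, outdir) -> dict:
    """Generate every pipeline input from a simulation config and write it.

    Returns the paths written (keys match :class:`PipelineConfig` path
    fields) so a pipeline run can be configured directly from the result.
    """
    from .simulate import (
        plant_truth,
        simulate_cohort,
        simulate_expression,
        simulate_marker_tracks,
        simulate_methylation,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = plant_truth(config)
    expr = simulate_expression(config, truth)
    beta, manifest = simulate_methylation(config, truth)
    tracks = simulate_marker_tracks(config, truth)
    cohort = simulate_cohort(config, truth)

    paths = {
        "expression_path": outdir / "expression.tsv",
        "expression_design_path": outdir / "expression_design.tsv",
        "beta_path": outdir / "beta.tsv",
        "beta_design_path": outdir / "beta_design.tsv",
        "manifest_path": outdir / "manifest.tsv",
        "gene_coords_path": outdir / "genes.tsv",
        "cohort_path": outdir / "cohort.tsv",
        "cohort_labels_path": outdir / "cohort_labels.tsv",
    }
    write_matrix_tsv(expr.values, paths["expression_path"])
    write_design_tsv(expr.design, paths["expression_design_path"])
    write_matrix_tsv(beta.values, paths["beta_path"])
    write_design_tsv(beta.design, paths["beta_design_path"])
    write_manifest_tsv(manifest, paths["manifest_path"])
    write_gene_coords_tsv(truth.gene_coords, paths["gene_coords_path"])
    write_cohort_tsv(cohort, paths["cohort_path"], paths["cohort_labels_path"])

    bed_dir = outdir / "tracks"
    bed_dir.mkdir(exist_ok=True)
    bed_paths = []
    for track in tracks:
        p = bed_dir / f"{track.cell_line}_{track.marker}.bed"
        write_bed(track, p)
        bed_paths.append(p)
    paths["bed_paths"] = bed_paths

    write_json(
        {
            "gene_class": truth.gene_class,
            "probe_class": truth.probe_class,
            "enhancer_probes": truth.enhancer_probes,
            "enhancer_dependency": truth.enhancer_dependency,
            "enhancer_targets": truth.enhancer_targets,
            "signature_genes": truth.signature_genes,
        },
        outdir / "truth.json",
    )
    paths["truth_path"] = outdir / "truth.json"
    return paths


# --- JSON helpers -----------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
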