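"""TSV / Newick readers and writers for the pipeline's tables."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .cohort import CohortData
from .defensin import DensitometryRecord
from .diversity import OtuTable, PhyloTree
from .histology import AxisMeasurement, SectionMeasurements

__all__ = [
    "write_cohort_tables",
    "read_histology_tables",
    "read_densitometry",
    "read_otu_table",
    "read_taxonomy",
    "read_tree",
]


def write_cohort_tables(data: CohortData, outdir: str | Path) -> dict[str, Path]:
    """Write every generated table; returns name -> path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    cohort = pd.DataFrame(
        {
            "mouse_id": [m.mouse_id for m in data.mice],
            "strain": [m.strain for m in data.mice],
            "age_weeks": [m.age_weeks for m in data.mice],
            "latent_severity": [m.latent_severity for m in data.mice],
        }
    )
    paths["cohort"] = out / "cohort.tsv"
    cohort.to_csv(paths["cohort"], sep="\t", index=False, float_format="%.10g")

    rows = []
    for m in data.mice:
        for a in m.section.axes:
            rows.append(
                {
                    "mouse_id": m.mouse_id,
                    "axis_index": a.axis_index,
                    "inflammatory_cells": a.inflammatory_cells,
                    "villus_length_um": a.villus_length,
                    "crypt_depth_um": a.crypt_depth,
                    "muscle_thickness_um": a.muscle_thickness,
                }
            )
    paths["histology_axes"] = out / "histology_axes.tsv"
    pd.DataFrame(rows).to_csv(
        paths["histology_axes"], sep="\t", index=False, float_format="%.10g"
    )

    mouse_rows = []
    for m in data.mice:
        eos = m.section.eosinophilic_positive_cells_per_axis
        mouse_rows.append(
            {
                "mouse_id": m.mouse_id,
                "crypt_abscess_count": m.section.crypt_abscess_count,
                "eosinophilic_cells_per_axis": ";".join(
                    f"{v:g}" for v in (eos or [])
                ),
            }
        )
    paths["histology_mouse"] = out / "histology_mouse.tsv"
    pd.DataFrame(mouse_rows).to_csv(paths["histology_mouse"], sep="\t", index=False)

    gel_rows = [
        {
            "sample_id": m.gel.sample_id,
            "standard_ng": m.gel.standard_ng,
            "standard_intensity": m.gel.standard_intensity,
            "trp_minus_intensity": m.gel.trp_minus_intensity,
            "trp_plus_intensity": m.gel.trp_plus_intensity,
            "feces_mass_normalizer": m.gel.feces_mass_normalizer,
        }
        for m in data.mice
    ]
    paths["densitometry"] = out / "densitometry.tsv"
    pd.DataFrame(gel_rows).to_csv(
        paths["densitometry"], sep="\t", index=False, float_format="%.10g"
    )

    paths["otu_table"] = out / "otu_table.tsv"
    data.otu_table.to_dataframe().rename_axis("sample_id").to_csv(
        paths["otu_table"], sep="\t"
    )

    paths["taxonomy"] = out / "taxonomy.tsv"
    pd.DataFrame(
        {"otu_id": list(data.taxonomy), "lineage": list(data.taxonomy.values())}
    ).to_csv(paths["taxonomy"], sep="\t", index=False)

    paths["tree"] = out / "tree.nwk"
    paths["tree"].write_text(data.tree_newick + "\n")
    return paths


def read_histology_tables(
    axes_path: str | Path, mouse_path: str | Path
) -> list[SectionMeasurements]:
    axes = pd.read_csv(axes_path, sep="\t")
    per_mouse = pd.read_csv(mouse_path, sep="\t").set_index("mouse_id")
    sections = []
    for mouse_id, grp in axes.groupby("mouse_id", sort=False):
        ax = [
            AxisMeasurement(
                int(r.axis_index),
                float(r.inflammatory_cells),
                float(r.villus_length_um),
                float(r.crypt_depth_um),
                float(r.muscle_thickness_um),
            )
            for r in grp.itertuples()
        ]
        abscess = 0
        eos = None
        if mouse_id in per_mouse.index:
            row = per_mouse.loc[mouse_id]
            abscess = int(row["crypt_abscess_count"])
            raw = row.get("eosinophilic_cells_per_axis", "")
            if isinstance(raw, str) and raw:
                eos = [float(v) for v in raw.split(";")]
        sections.append(SectionMeasurements(str(mouse_id), ax, abscess, eos))
    return sections


def read_densitometry(path: str | Path) -> list[DensitometryRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        DensitometryRecord(
            sample_id=str(r.sample_id),
            standard_ng=float(r.standard_ng),
            standard_intensity=float(r.standard_intensity),
            trp_minus_intensity=float(r.trp_minus_intensity),
            trp_plus_intensity=float(r.trp_plus_intensity),
            feces_mass_normalizer=float(getattr(r, "feces_mass_normalizer", 500.0)),
        )
        for r in df.itertuples()
    ]


def read_otu_table(path: str | Path) -> OtuTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return OtuTable.from_dataframe(df)


def read_taxonomy(path: str | Path) -> Mapping[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["otu_id"].astype(str), df["lineage"].astype(str)))


def read_tree(path: str | Path) -> PhyloTree:
    return PhyloTree.from_newick(Path(path).read_text().strip())
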