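"""Reading and writing the pipeline's tabular interchange formats.

Cell tables are CSV with columns: cell_id, image_id, x_um, y_um,
area_um2, phenotype, compartment, ki67_positive, mask_overlap_fraction,
plus one column per marker channel. Contacts are a CSV of
(image_id, cell_a, cell_b); sample/image metadata are CSV; the synthetic
truth table is JSON; label masks are single-plane 16-bit TIFF.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .features import ContactGraph
from .simulate import Cohort

logger = logging.getLogger(__name__)

REQUIRED_CELL_COLUMNS = ("cell_id", "image_id", "x_um", "y_um", "area_um2", "phenotype")


class SchemaError(ValueError):
    """Raised when input tables violate the documented schema."""


def read_cell_tables(path: str | Path) -> dict[str, pd.DataFrame]:
    """Read a combined cell CSV into per-image tables, validating schema.

    Collects all violations (missing columns, duplicate cell ids within
    an image, non-numeric coordinates) and reports them together.
    """
    df = pd.read_csv(path)
    problems: list[str] = []
    missing = [c for c in REQUIRED_CELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    for col in ("x_um", "y_um", "area_um2"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            problems.append(f"non-numeric {col} in rows {df.index[bad].tolist()[:5]}")
        df[col] = pd.to_numeric(df[col], errors="coerce")
    out: dict[str, pd.DataFrame] = {}
    for img, sub in df.groupby("image_id", sort=True):
        dup = sub["cell_id"].duplicated()
        if dup.any():
            problems.append(f"duplicate cell_id in image {img!r}")
            continue
        out[str(img)] = sub.drop(columns="image_id").reset_index(drop=True)
        logger.info("image %s: %d cells", img, len(sub))
    if problems:
        raise SchemaError(f"{path}: " + "; ".join(problems))
    if not out:
        logger.warning("%s: no cells found (empty cohort)", path)
    return out


def write_cell_tables(cells: Mapping[str, pd.DataFrame], path: str | Path) -> None:
    frames = []
    for img, t in cells.items():
        t = t.copy()
        t.insert(1, "image_id", img)
        frames.append(t)
    combined = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=REQUIRED_CELL_COLUMNS)
    )
    combined.to_csv(path, index=False)


def write_contacts(contacts: Mapping[str, ContactGraph], path: str | Path) -> None:
    rows = [
        {"image_id": img, "cell_a": a, "cell_b": b}
        for img, g in contacts.items()
        for a, b in sorted(g.edges)
    ]
    pd.DataFrame(rows, columns=["image_id", "cell_a", "cell_b"]).to_csv(
        path, index=False
    )


def read_contacts(path: str | Path) -> dict[str, ContactGraph]:
    df = pd.read_csv(path)
    out = {}
    for img, sub in df.groupby("image_id", sort=True):
        out[str(img)] = ContactGraph.from_pairs(
            str(img), zip(sub["cell_a"].astype(int), sub["cell_b"].astype(int))
        )
    return out


def write_spillover(S: np.ndarray, channels: list[str], path: str | Path) -> None:
    pd.DataFrame(S, index=channels, columns=channels).to_csv(path)


def read_spillover(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise SchemaError("spillover matrix must be square with matching labels")
    return df.to_numpy(dtype=float), list(df.columns)


def write_label_mask(mask: np.ndarray, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(path, mask.astype(np.uint16))


def read_label_mask(path: str | Path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Persist a synthetic cohort as the standard pipeline inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_cell_tables(cohort.cells, outdir / "cells.csv")
    write_contacts(cohort.contacts, outdir / "contacts.csv")
    cohort.samples.to_csv(outdir / "samples.csv", index=False)
    cohort.images.to_csv(outdir / "images.csv", index=False)
    truth = {
        "features": json.loads(cohort.truth["features"].to_json(orient="index")),
        "response": cohort.truth["response"].to_dict(),
        "p_pcr": cohort.truth["p_pcr"].to_dict(),
        "response_intercept": cohort.truth["response_intercept"],
        "effect_spec": [e.__dict__ for e in cohort.truth["effect_spec"]],
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
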