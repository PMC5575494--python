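"""Cohort manifest / ratings-table file I/O.

A cohort on disk is one directory:

    manifest.json        registry of images -> observers -> contour files
    ratings.csv          image_id, session1, session2
    meshes/*.ply         contours (ascii PLY, mm, L/A/S frame)

The manifest records the full generator config and master seed so the
cohort is reproducible bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .meshfiles import read_contour, write_ply

MANIFEST_SCHEMA = "agree3d-cohort/1"


def write_cohort(cohort, out_dir) -> Path:
    """Write meshes, ratings.csv and manifest.json for a cohort built by
    :func:`agree3d.synthetic.build_cohort`.  Returns the manifest path."""
    out = Path(out_dir)
    mesh_dir = out / "meshes"
    mesh_dir.mkdir(parents=True, exist_ok=True)

    entries = []
    ratings_rows = []
    for img in cohort.images:
        true_rel = f"meshes/{img.image_id}_true.ply"
        write_ply(img.true_shape, out / true_rel)
        manual = []
        for obs, c in img.manual.items():
            rel = f"meshes/{img.image_id}_{obs}_manual.ply"
            write_ply(c, out / rel)
            manual.append({"observer": obs, "path": rel})
        ags = []
        for obs, c in img.ags.items():
            if c is None:
                ags.append({"observer": obs, "status": "failure", "path": None})
            else:
                rel = f"meshes/{img.image_id}_{obs}_ags.ply"
                write_ply(c, out / rel)
                ags.append({"observer": obs, "status": "success", "path": rel})
        entries.append(
            {
                "image_id": img.image_id,
                "final_rating": img.final_rating,
                "session_ratings": list(img.session_ratings),
                "true_shape": true_rel,
                "shape_params": {
                    k: v for k, v in vars(img.shape_params).items()
                },
                "manual": manual,
                "ags": ags,
            }
        )
        ratings_rows.append(
            {"image_id": img.image_id,
             "session1": img.session_ratings[0],
             "session2": img.session_ratings[1]}
        )
    for image_id, sessions in cohort.excluded:
        ratings_rows.append(
            {"image_id": image_id, "session1": sessions[0], "session2": sessions[1]}
        )
    ratings_rows.sort(key=lambda r: r["image_id"])

    manifest = {
        "schema": MANIFEST_SCHEMA,
        "master_seed": cohort.master_seed,
        "config": cohort.config.to_dict(),
        "conventions": {
            "units": "mm",
            "frame": "+x Left, +y Anterior, +z Superior",
            "rating_rounding": "round-half-up of two-session mean",
            "exclusion": "any session rating of 0 excludes the image",
        },
        "excluded_images": [
            {"image_id": i, "session_ratings": list(s)} for i, s in cohort.excluded
        ],
        "images": entries,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    pd.DataFrame(ratings_rows).to_csv(out / "ratings.csv", index=False)
    return out / "manifest.json"


def load_manifest(manifest_path) -> dict:
    path = Path(manifest_path)
    try:
        manifest = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValidationError(f"cannot load manifest {path}: {exc}") from exc
    if manifest.get("schema") != MANIFEST_SCHEMA:
        raise ValidationError(
            f"{path}: unknown manifest schema {manifest.get('schema')!r}"
        )
    manifest["_root"] = path.parent
    return manifest


def load_image_contours(manifest: dict, entry: dict):
    """Load (manual, ags) contour dicts for one manifest image entry."""
    root = manifest["_root"]
    manual = {
        m["observer"]: read_contour(
            root / m["path"], image_id=entry["image_id"],
            delineator=m["observer"], method="manual",
        )
        for m in entry["manual"]
    }
    ags = {}
    for a in entry["ags"]:
        if a["status"] == "success":
            ags[a["observer"]] = read_contour(
                root / a["path"], image_id=entry["image_id"],
                delineator=a["observer"], method="ags",
            )
        else:
            ags[a["observer"]] = None
    return manual, ags


def read_ratings(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"image_id", "session1", "session2"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"ratings table must have columns {sorted(required)}"
        )
    return df
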