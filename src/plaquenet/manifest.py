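"""On-disk dataset manifest: the contract between pipeline stages.

A manifest is an ordered table with one row per image:
``sample_id, image_path, mask_path, long_mm, short_mm, spacing_mm_per_px,
split`` where paths are relative to the manifest's directory and ``split``
is one of ``train/val/test/unassigned``.  It is written both as CSV and
JSON; the CSV is authoritative for reading.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

COLUMNS = ["sample_id", "image_path", "mask_path", "long_mm", "short_mm",
           "spacing_mm_per_px", "split"]
SPLITS = ("train", "val", "test", "unassigned")

__all__ = ["DatasetManifest", "ManifestError", "COLUMNS", "SPLITS"]


class ManifestError(ValueError):
    pass


@dataclass
class DatasetManifest:
    rows: pd.DataFrame
    root: Path = Path(".")
    provenance: str = ""

    def __post_init__(self) -> None:
        self.root = Path(self.root)
        missing = [c for c in COLUMNS if c not in self.rows.columns]
        if missing:
            raise ManifestError(f"manifest missing columns: {missing}")
        self.rows = self.rows[COLUMNS].reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        ids = self.rows["sample_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ManifestError(f"duplicate sample_id: {dup!r}")
        bad = set(self.rows["split"]) - set(SPLITS)
        if bad:
            raise ManifestError(f"unknown split labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.rows)

    def counts(self) -> dict[str, int]:
        """Row count per split."""
        c = self.rows["split"].value_counts().to_dict()
        return {s: int(c.get(s, 0)) for s in SPLITS}

    def subset(self, split: str) -> pd.DataFrame:
        return self.rows[self.rows["split"] == split].reset_index(drop=True)

    # ---- image access -------------------------------------------------------

    def load_image(self, row) -> np.ndarray:
        """8-bit grayscale image as float in [0, 1]."""
        arr = np.asarray(Image.open(self.root / row.image_path), dtype=np.float64)
        return arr / 255.0

    def load_mask(self, row) -> np.ndarray:
        arr = np.asarray(Image.open(self.root / row.mask_path))
        return (arr != 0).astype(np.uint8)

    # ---- persistence --------------------------------------------------------

    def write(self, directory: Path | None = None, stem: str = "manifest") -> Path:
        """Write CSV + JSON copies; returns the CSV path."""
        directory = Path(directory) if directory is not None else self.root
        directory.mkdir(parents=True, exist_ok=True)
        csv_path = directory / f"{stem}.csv"
        self.rows.to_csv(csv_path, index=False)
        payload = {"provenance": self.provenance,
                   "rows": self.rows.to_dict(orient="records")}
        (directory / f"{stem}.json").write_text(json.dumps(payload, indent=1))
        return csv_path

    @classmethod
    def read(cls, csv_path) -> "DatasetManifest":
        csv_path = Path(csv_path)
        df = pd.read_csv(csv_path, dtype={"sample_id": str, "split": str})
        if len(df) == 0:
            df = pd.DataFrame(columns=COLUMNS)
        prov = ""
        jp = csv_path.with_suffix(".json")
        if jp.exists():
            prov = json.loads(jp.read_text()).get("provenance", "")
        return cls(rows=df, root=csv_path.parent, provenance=prov)
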