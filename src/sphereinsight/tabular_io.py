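"""On-disk formats: OTU/ASV count tables, label files, image stacks, configs.

Count tables are TSV with a header row of taxon identifiers and the sample
identifier in the first column (comma dialect behind a flag). Image stacks are
compressed NPZ archives carrying the float images, the shared foreground mask
and rendering metadata; PNG previews are cosmetic only and never the training
input.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import FormatError, ValidationError

logger = logging.getLogger("sphereinsight")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


@dataclass
class CountTable:
    """Samples x taxa nonnegative integer counts with identifiers."""

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (
            len(self.sample_ids),
            len(self.taxon_ids),
        ):
            raise ValidationError("count matrix shape does not match identifier lists")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample identifiers")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValidationError("duplicate taxon identifiers")
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        row_sums = self.counts.sum(axis=1)
        if np.any(row_sums == 0):
            i = int(np.nonzero(row_sums == 0)[0][0])
            raise ValidationError(
                f"sample {self.sample_ids[i]!r} has no positive counts"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class LabelVector:
    """Binary class labels aligned with a CountTable's samples."""

    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.sample_ids),):
            raise ValidationError("label vector length does not match sample ids")
        if not np.all(np.isin(self.labels, [0, 1])):
            raise ValidationError("labels must be binary {0,1}")


def read_count_table(path, sep: str = "\t") -> CountTable:
    """Parse a count table: header of taxon ids, first column sample ids.

    Row and column order are preserved; any negative or non-numeric cell is a
    format error naming the offending position.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no taxon columns found (wrong separator?)")
    sample_ids = [str(s) for s in df.index]
    taxon_ids = [str(t) for t in df.columns]
    try:
        counts = df.to_numpy(dtype=np.int64)
    except ValueError:
        # locate the first bad cell for the error message
        for i, row in enumerate(df.itertuples(index=False)):
            for j, cell in enumerate(row):
                try:
                    int(cell)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"{path}: non-numeric value {cell!r} at sample "
                        f"{sample_ids[i]!r}, taxon {taxon_ids[j]!r}"
                    ) from None
        raise
    if np.any(counts < 0):
        i, j = np.argwhere(counts < 0)[0]
        raise FormatError(
            f"{path}: negative value at sample {sample_ids[i]!r}, "
            f"taxon {taxon_ids[j]!r}"
        )
    table = CountTable(sample_ids=sample_ids, taxon_ids=taxon_ids, counts=counts)
    logger.info("read count table %s: %d samples x %d taxa", path, *table.shape)
    return table


def write_count_table(table: CountTable, path, sep: str = "\t") -> None:
    df = pd.DataFrame(table.counts, index=table.sample_ids, columns=table.taxon_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep)


def read_labels(path, sep: str = "\t") -> LabelVector:
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] != 2:
        raise FormatError(f"{path}: expected two columns (sample_id, label)")
    return LabelVector(
        sample_ids=[str(s) for s in df.iloc[:, 0]],
        labels=df.iloc[:, 1].to_numpy(dtype=int),
    )


def write_labels(labels: LabelVector, path, sep: str = "\t") -> None:
    pd.DataFrame(
        {"sample_id": labels.sample_ids, "label": labels.labels}
    ).to_csv(path, sep=sep, index=False)


def write_image_stack(stack, path, preview: bool = False) -> None:
    """Serialize an ImageStack to compressed NPZ (+ optional PNG previews).

    The NPZ holds the float images (training fidelity), the foreground mask and
    a JSON metadata member (epsilon, normalization scheme, grid size). Previews
    are min-max rescaled 8-bit grayscale PNGs for human eyes only — an all-ε
    foreground would be invisibly dark otherwise — and are never read back.
    """
    if stack.images.shape[0] == 0:
        raise ValidationError("refusing to write an empty image stack")
    path = Path(path)
    meta = {
        "epsilon": stack.epsilon,
        "normalization_scheme": stack.normalization_scheme,
        "grid_h": int(stack.images.shape[1]),
        "grid_w": int(stack.images.shape[2]),
    }
    np.savez_compressed(
        path,
        images=stack.images,
        foreground_mask=stack.foreground_mask,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )
    if preview:
        from PIL import Image

        preview_dir = path.with_suffix("").parent / (path.stem + "_previews")
        preview_dir.mkdir(parents=True, exist_ok=True)
        for i, img in enumerate(stack.images):
            lo, hi = float(img.min()), float(img.max())
            scaled = (img - lo) / (hi - lo) if hi > lo else (img > 0).astype(float)
            Image.fromarray((scaled * 255).round().astype(np.uint8), mode="L").save(
                preview_dir / f"sample_{i:04d}.png"
            )
        logger.info("wrote %d preview PNGs to %s", len(stack.images), preview_dir)


def read_image_stack(path):
    from .insight_imaging import ImageStack

    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta"]).decode())
        return ImageStack(
            images=npz["images"],
            foreground_mask=npz["foreground_mask"],
            epsilon=meta["epsilon"],
            normalization_scheme=meta["normalization_scheme"],
        )


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
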