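"""Array layout: the printed design of a reverse-phase protein array.

A layout describes the block/row/column lattice of printed spots, the
physical pitch between spot centers, and the biological annotation of every
spot (which sample, which step of its serial dilution, which replicate).

Conventions used throughout the package
---------------------------------------
* Pixel coordinates are 0-based, row-major ``(y, x)`` with y increasing
  downward; pixel centers sit at integer coordinates.
* Micron -> pixel conversions always go through ``pixel_size`` (µm/pixel).
* Dilution step ``k`` of a 1:``base`` series has relative concentration
  (dilution factor) ``base**-k``; the top concentration is step 0, factor 1.

The on-disk format is a self-describing JSON document (see
:func:`read_layout` / :func:`write_layout`); a schema example ships in the
repository README.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .errors import LayoutValidationError

ROLES = ("sample", "control", "empty")


@dataclass(frozen=True)
class SpotAnnotation:
    """Annotation of a single printed spot.

    Parameters
    ----------
    address
        ``(block, row, col)`` with a linear 0-based block index.
    sample_id
        Label of the lysate printed at this spot ("" for empty spots).
    dilution_step
        0-based step of the serial dilution (0 = most concentrated).
    dilution_factor
        Relative concentration, ``base**-dilution_step`` for the layout's
        dilution base.
    replicate
        1-based replicate index within the dilution series.
    role
        One of ``sample``, ``control``, ``empty``.
    """

    address: tuple[int, int, int]
    sample_id: str = ""
    dilution_step: int = 0
    dilution_factor: float = 1.0
    replicate: int = 1
    role: str = "sample"

    def __post_init__(self):
        if self.role not in ROLES:
            raise LayoutValidationError(
                f"unknown role {self.role!r} at {self.address}", [self]
            )
        if self.role == "sample":
            if self.dilution_step < 0:
                raise LayoutValidationError(
                    f"negative dilution step at {self.address}", [self]
                )
            if self.dilution_factor <= 0:
                raise LayoutValidationError(
                    f"non-positive dilution factor at {self.address}", [self]
                )
            if self.replicate < 1:
                raise LayoutValidationError(
                    f"replicate must be >= 1 at {self.address}", [self]
                )

    @property
    def series_id(self) -> str:
        """Dilution series this spot belongs to (one series per sample)."""
        return self.sample_id


@dataclass(frozen=True)
class ArrayLayout:
    """Printed grid geometry plus per-spot annotations.

    Blocks (one per print pin) are arranged in an
    ``n_block_rows x n_block_cols`` super-grid; adjacent blocks are
    separated by ``block_gap`` extra pitches.
    """

    n_block_rows: int
    n_block_cols: int
    rows_per_block: int
    cols_per_block: int
    pitch: float  # µm, center-to-center
    pixel_size: float  # µm / pixel
    origin: tuple[float, float]  # (y, x) pixels of the first nominal center
    spots: tuple[SpotAnnotation, ...] = ()
    dilution_base: float = 2.0
    block_gap: float = 1.0  # extra pitches between blocks

    def __post_init__(self):
        if self.pitch <= 0:
            raise LayoutValidationError(f"pitch must be > 0, got {self.pitch}")
        if self.pixel_size <= 0:
            raise LayoutValidationError(
                f"pixel_size must be > 0, got {self.pixel_size}"
            )
        seen: dict[tuple[int, int, int], SpotAnnotation] = {}
        dupes = []
        n_blocks = self.n_block_rows * self.n_block_cols
        bad_addr = []
        for s in self.spots:
            b, r, c = s.address
            if not (0 <= b < n_blocks and 0 <= r < self.rows_per_block
                    and 0 <= c < self.cols_per_block):
                bad_addr.append(s)
            if s.address in seen:
                dupes.append(s)
            seen[s.address] = s
        if dupes:
            raise LayoutValidationError(
                f"duplicate spot addresses: {[s.address for s in dupes]}", dupes
            )
        if bad_addr:
            raise LayoutValidationError(
                f"addresses outside grid: {[s.address for s in bad_addr]}",
                bad_addr,
            )
        missing_sample = [s for s in self.spots
                          if s.role == "sample" and not s.sample_id]
        if missing_sample:
            raise LayoutValidationError(
                "sample spots without a sample_id: "
                f"{[s.address for s in missing_sample]}", missing_sample
            )

    # -- geometry -----------------------------------------------------------

    @property
    def pitch_px(self) -> float:
        return self.pitch / self.pixel_size

    def nominal_center(self, address: tuple[int, int, int]) -> tuple[float, float]:
        """Nominal ``(y, x)`` pixel center of the spot at ``address``."""
        b, r, c = address
        br, bc = divmod(b, self.n_block_cols)
        row_idx = br * (self.rows_per_block + self.block_gap) + r
        col_idx = bc * (self.cols_per_block + self.block_gap) + c
        return (self.origin[0] + row_idx * self.pitch_px,
                self.origin[1] + col_idx * self.pitch_px)

    def nominal_centers(self) -> np.ndarray:
        """``(n_spots, 2)`` array of (y, x) nominal centers, in spot order."""
        return np.array([self.nominal_center(s.address) for s in self.spots],
                        dtype=float).reshape(-1, 2)

    def frame_shape(self, margin_pitches: float = 1.0) -> tuple[int, int]:
        """Smallest (height, width) frame holding all spots plus margin."""
        centers = self.nominal_centers()
        if len(centers) == 0:
            return (int(np.ceil(2 * margin_pitches * self.pitch_px)),) * 2
        m = margin_pitches * self.pitch_px
        h = int(np.ceil(centers[:, 0].max() + m)) + 1
        w = int(np.ceil(centers[:, 1].max() + m)) + 1
        return h, w

    # -- annotation views ---------------------------------------------------

    def sample_spots(self) -> Iterator[SpotAnnotation]:
        return (s for s in self.spots if s.role == "sample")

    def series(self) -> dict[str, list[SpotAnnotation]]:
        """Spots grouped by dilution series, insertion-ordered."""
        out: dict[str, list[SpotAnnotation]] = {}
        for s in self.sample_spots():
            out.setdefault(s.series_id, []).append(s)
        return out


def make_dilution_layout(
    sample_ids,
    n_steps: int = 5,
    n_replicates: int = 3,
    dilution_base: float = 2.0,
    pitch: float = 350.0,
    pixel_size: float = 10.0,
    origin: tuple[float, float] | None = None,
    n_block_cols: int = 1,
) -> ArrayLayout:
    """Build the standard serial-dilution layout used on these arrays.

    Each sample occupies one block row: ``n_steps`` serial dilutions
    (1, 1/base, 1/base^2, ...) printed ``n_replicates`` times, replicates
    laid out as consecutive column groups.  With the defaults (5 steps,
    triplicate, 1:2) every sample contributes 15 spots, mirroring the
    printed design the pipeline targets.
    """
    sample_ids = list(sample_ids)
    pitch_px = pitch / pixel_size
    if origin is None:
        origin = (pitch_px, pitch_px)
    spots = []
    for i, sid in enumerate(sample_ids):
        for rep in range(n_replicates):
            for step in range(n_steps):
                col = rep * n_steps + step
                spots.append(SpotAnnotation(
                    address=(0, i, col),
                    sample_id=str(sid),
                    dilution_step=step,
                    dilution_factor=float(dilution_base) ** (-step),
                    replicate=rep + 1,
                    role="sample",
                ))
    return ArrayLayout(
        n_block_rows=1, n_block_cols=n_block_cols,
        rows_per_block=len(sample_ids), cols_per_block=n_steps * n_replicates,
        pitch=pitch, pixel_size=pixel_size, origin=origin,
        spots=tuple(spots), dilution_base=dilution_base,
    )


# -- serialization ----------------------------------------------------------

def layout_to_dict(layout: ArrayLayout) -> dict:
    return {
        "n_block_rows": layout.n_block_rows,
        "n_block_cols": layout.n_block_cols,
        "rows_per_block": layout.rows_per_block,
        "cols_per_block": layout.cols_per_block,
        "pitch_um": layout.pitch,
        "pixel_size_um": layout.pixel_size,
        "origin_px": list(layout.origin),
        "dilution_base": layout.dilution_base,
        "block_gap": layout.block_gap,
        "spots": [
            {
                "block": s.address[0], "row": s.address[1], "col": s.address[2],
                "sample_id": s.sample_id, "dilution_step": s.dilution_step,
                "dilution_factor": s.dilution_factor,
                "replicate": s.replicate, "role": s.role,
            }
            for s in layout.spots
        ],
    }


def layout_from_dict(doc: dict) -> ArrayLayout:
    base = float(doc.get("dilution_base", 2.0))
    spots = []
    for rec in doc.get("spots", []):
        step = int(rec.get("dilution_step", 0))
        factor = rec.get("dilution_factor")
        if factor is None:
            factor = base ** (-step)
        spots.append(SpotAnnotation(
            address=(int(rec["block"]), int(rec["row"]), int(rec["col"])),
            sample_id=str(rec.get("sample_id", "")),
            dilution_step=step,
            dilution_factor=float(factor),
            replicate=int(rec.get("replicate", 1)),
            role=str(rec.get("role", "sample")),
        ))
    return ArrayLayout(
        n_block_rows=int(doc["n_block_rows"]),
        n_block_cols=int(doc["n_block_cols"]),
        rows_per_block=int(doc["rows_per_block"]),
        cols_per_block=int(doc["cols_per_block"]),
        pitch=float(doc["pitch_um"]),
        pixel_size=float(doc["pixel_size_um"]),
        origin=tuple(float(v) for v in doc["origin_px"]),
        spots=tuple(spots),
        dilution_base=base,
        block_gap=float(doc.get("block_gap", 1.0)),
    )


def read_layout(path) -> ArrayLayout:
    """Read an array layout from its JSON description."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise LayoutValidationError(f"not valid JSON: {path}: {e}") from e
    try:
        return layout_from_dict(doc)
    except (KeyError, TypeError, ValueError) as e:
        raise LayoutValidationError(f"malformed layout {path}: {e}") from e


def write_layout(layout: ArrayLayout, path):
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(layout_to_dict(layout), fh, indent=1)
    return path
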