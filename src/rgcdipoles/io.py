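"""Readers and writers for mosaic point files, OPM grids and configurations.

The labelled-xy mosaic format is whitespace-delimited text with columns
``x_um y_um polarity``, '#'-prefixed comments and an optional
``# window x0 x1 y0 y1`` header.  Polarity labels {on, off, 1, -1} are
accepted case-insensitively.  Archive mosaics distributed as separate ON
and OFF coordinate files are supported through the ``paired-files``
dialect.
"""
from __future__ import annotations

from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import yaml

from .core import (
    InteractionParams,
    MosaicFormatError,
    MPIPPConfig,
    PairRepulsion,
    PointMosaic,
)
from .opm import OrientationField

__all__ = [
    "read_mosaic",
    "write_mosaic",
    "load_config",
    "save_config",
    "read_opm",
    "write_opm",
]

_ON_LABELS = {"on", "1", "+1"}
_OFF_LABELS = {"off", "-1"}


def _parse_labelled_xy(path: Path):
    on, off, window = [], [], None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                tokens = line[1:].split()
                if tokens and tokens[0].lower() == "window":
                    if len(tokens) != 5:
                        raise MosaicFormatError(
                            f"{path}, line {lineno}: window header needs 4 numbers")
                    try:
                        window = tuple(float(t) for t in tokens[1:])
                    except ValueError as exc:
                        raise MosaicFormatError(
                            f"{path}, line {lineno}: unparseable window header") from exc
                continue
            tokens = line.split()
            if len(tokens) != 3:
                raise MosaicFormatError(
                    f"{path}, line {lineno}: expected 'x y polarity', got {line!r}")
            try:
                x, y = float(tokens[0]), float(tokens[1])
            except ValueError as exc:
                raise MosaicFormatError(
                    f"{path}, line {lineno}: unparseable coordinates {line!r}") from exc
            label = tokens[2].lower()
            if label in _ON_LABELS:
                on.append((x, y))
            elif label in _OFF_LABELS:
                off.append((x, y))
            else:
                raise ValueError(
                    f"{path}, line {lineno}: unknown polarity label {tokens[2]!r} "
                    "(accepted: on, off, 1, -1)")
    return on, off, window


def _parse_xy(path: Path):
    pts = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise MosaicFormatError(
                    f"{path}, line {lineno}: expected 'x y', got {line!r}")
            try:
                pts.append((float(tokens[0]), float(tokens[1])))
            except ValueError as exc:
                raise MosaicFormatError(
                    f"{path}, line {lineno}: unparseable coordinates {line!r}") from exc
    return pts


def read_mosaic(path, dialect: str = "labelled-xy",
                off_path=None) -> PointMosaic:
    """Read a mosaic point file.

    ``dialect='labelled-xy'`` expects a single file with columns
    ``x y polarity``; ``dialect='paired-files'`` expects *path* to hold the
    ON coordinates and *off_path* the OFF coordinates (two columns each).
    The window is taken from a ``# window`` header when present, otherwise
    from the bounding box of the points.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "labelled-xy":
        on, off, window = _parse_labelled_xy(path)
    elif dialect == "paired-files":
        if off_path is None:
            raise ValueError("dialect 'paired-files' requires off_path")
        on, off, window = _parse_xy(path), _parse_xy(Path(off_path)), None
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if window is not None:
        return PointMosaic(on, off, window)
    return PointMosaic.from_points(on, off)


def write_mosaic(mosaic: PointMosaic, path) -> None:
    """Write a mosaic in labelled-xy format (re-readable by read_mosaic).

    Coordinates are printed at 6 significant digits; the window travels in
    a comment header.  An empty mosaic produces a header-only file.
    """
    path = Path(path)
    x0, x1, y0, y1 = mosaic.window
    lines = [
        "# rgcdipoles mosaic (x_um y_um polarity)",
        f"# window {x0:.6g} {x1:.6g} {y0:.6g} {y1:.6g}",
    ]
    for x, y in mosaic.on_points:
        lines.append(f"{x:.6g} {y:.6g} on")
    for x, y in mosaic.off_points:
        lines.append(f"{x:.6g} {y:.6g} off")
    path.write_text("\n".join(lines) + "\n")


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ValueError(f"config field {context}.{key} is missing")
    return mapping[key]


def _pair_from_dict(d: dict, name: str, step_only: bool = False) -> PairRepulsion:
    try:
        if step_only:
            return PairRepulsion(delta=float(_require(d, "delta", name)))
        return PairRepulsion(delta=float(_require(d, "delta", name)),
                             phi=float(_require(d, "phi", name)),
                             alpha=float(_require(d, "alpha", name)))
    except ValueError as exc:
        raise ValueError(f"invalid interaction parameters in {name!r}: {exc}") from exc


def load_config(path) -> Tuple[InteractionParams, MPIPPConfig]:
    """Load interaction and model parameters from a YAML config file.

    Missing optional model fields take documented defaults (beta = 0,
    n_sweeps = 20).  Invalid values raise a validation error naming the
    offending field.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "interactions" not in doc:
        raise ValueError(f"{path}: config must contain an 'interactions' section")
    inter = doc["interactions"]
    params = InteractionParams(
        on_on=_pair_from_dict(_require(inter, "on_on", "interactions"), "interactions.on_on"),
        off_off=_pair_from_dict(_require(inter, "off_off", "interactions"), "interactions.off_off"),
        on_off=_pair_from_dict(_require(inter, "on_off", "interactions"), "interactions.on_off",
                               step_only=True),
    )
    model = doc.get("model", {}) or {}
    try:
        cfg = MPIPPConfig(
            beta=float(model.get("beta", 0.0)),
            d_mod=float(model.get("d_mod", 80.0)),
            n_sweeps=int(model.get("n_sweeps", 20)),
            magnification=float(model.get("magnification", 1.7)),
            seed=int(model.get("seed", 0)),
        )
    except ValueError as exc:
        raise ValueError(f"invalid model parameters: {exc}") from exc
    if not cfg.d_mod > params.soma_diameter:
        raise ValueError("model.d_mod must exceed interactions.on_off.delta (soma diameter)")
    return params, cfg


def save_config(params: InteractionParams, cfg: MPIPPConfig, path) -> None:
    """Write a config file that round-trips through :func:`load_config`."""
    doc = {
        "interactions": {
            "on_on": {"delta": params.on_on.delta, "phi": params.on_on.phi,
                      "alpha": params.on_on.alpha},
            "off_off": {"delta": params.off_off.delta, "phi": params.off_off.phi,
                        "alpha": params.off_off.alpha},
            "on_off": {"delta": params.on_off.delta},
        },
        "model": {"beta": cfg.beta, "d_mod": cfg.d_mod, "n_sweeps": cfg.n_sweeps,
                  "magnification": cfg.magnification, "seed": cfg.seed},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def write_opm(field: OrientationField, path) -> None:
    """Store an orientation field as plain-matrix text with a metadata header."""
    path = Path(path)
    header = (
        f"pixel_size {field.pixel_size:.9g}\n"
        f"column_spacing {field.column_spacing:.9g}\n"
        f"magnification {field.magnification:.9g}\n"
        f"origin {field.origin[0]:.9g} {field.origin[1]:.9g}"
    )
    np.savetxt(path, field.angles, fmt="%.9g", header=header)


def read_opm(path) -> OrientationField:
    """Read an orientation field written by :func:`write_opm`."""
    path = Path(path)
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            tokens = line[1:].split()
            if tokens:
                meta[tokens[0]] = [float(t) for t in tokens[1:]]
    for key in ("pixel_size", "column_spacing", "magnification", "origin"):
        if key not in meta:
            raise MosaicFormatError(f"{path}: missing OPM header field {key!r}")
    angles = np.loadtxt(path)
    return OrientationField(
        np.atleast_2d(angles),
        pixel_size=meta["pixel_size"][0],
        column_spacing=meta["column_spacing"][0],
        magnification=meta["magnification"][0],
        origin=(meta["origin"][0], meta["origin"][1]),
    )
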