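"""Flat key=value run configuration with lossless round-trip.

One plain-text file drives the whole benchmark: phantom geometry,
measure scales, MSM quantile, tensor parameters, solver settings and the
noise schedule.  Every key can be overridden by a CLI flag.  The format
is deliberately minimal — ``key = value`` lines, ``#`` comments, tuples
as comma-separated lists — so configs stay diffable and hand-editable.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field, fields

from .errors import DataError
from .multifractal import MeasureConfig
from .phantom import PhantomSpec
from .reconstruct import DenoiseConfig, SolverConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one benchmark run."""

    # phantom geometry
    height: int = 128
    width: int = 128
    n_cells: int = 8
    n_clusters: int = 3
    n_subcellular_objects: int = 4
    cell_radius_range: tuple[float, float] = (10.0, 16.0)
    nucleus_fraction: float = 0.45
    particle_radius_range: tuple[float, float] = (1.5, 3.0)
    intensity_levels: tuple[float, float, float] = (0.8, 0.9, 1.0)
    blur_sigma: float = 1.0
    # measure / feature extraction
    scales: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    gammas: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
    density_mode: str = "gradient_magnitude"
    kernel_truncation: float = 3.0
    msm_quantile: float = 0.25
    # diffusion tensor
    use_identity_tensor: bool = False
    tensor_sigma: float = 1.5
    tensor_k: float = 0.0  # 0 means "auto" (90th percentile)
    iso_floor: float = 0.05
    # solver
    tol: float = 1e-8
    max_iter: int = 10_000
    # experiment design
    noise_levels: tuple[float, ...] = (1e-3, 10**-2.5, 1e-2, 10**-1.5, 1e-1)
    n_datasets: int = 5
    psd_bins: int = 32
    seed: int = 0
    verbosity: int = 1

    def phantom_spec(self, seed: int | None = None) -> PhantomSpec:
        return PhantomSpec(
            height=self.height,
            width=self.width,
            n_cells=self.n_cells,
            n_clusters=self.n_clusters,
            n_subcellular_objects=self.n_subcellular_objects,
            cell_radius_range=self.cell_radius_range,
            nucleus_fraction=self.nucleus_fraction,
            particle_radius_range=self.particle_radius_range,
            intensity_levels=self.intensity_levels,
            blur_sigma=self.blur_sigma,
            seed=self.seed if seed is None else seed,
        )

    def denoise_config(self) -> DenoiseConfig:
        return DenoiseConfig(
            measure=MeasureConfig(
                scales=self.scales,
                gammas=self.gammas,
                density_mode=self.density_mode,
                kernel_truncation=self.kernel_truncation,
            ),
            msm_quantile=self.msm_quantile,
            use_identity_tensor=self.use_identity_tensor,
            tensor_sigma=self.tensor_sigma,
            tensor_k=None if self.tensor_k == 0 else self.tensor_k,
            iso_floor=self.iso_floor,
            solver=SolverConfig(tol=self.tol, max_iter=self.max_iter),
        )


def _format_value(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, tuple):
        return ", ".join(repr(v) for v in value)
    return repr(value)


def _parse_value(text: str, kind):
    text = text.strip()
    if kind is bool:
        if text.lower() in ("true", "1", "yes"):
            return True
        if text.lower() in ("false", "0", "no"):
            return False
        raise DataError(f"cannot parse boolean from {text!r}")
    if kind is int:
        return int(text)
    if kind is float:
        return float(text)
    if kind is str:
        return text.strip("'\"")
    # tuples: comma-separated, element type from the annotation
    origin = getattr(kind, "__origin__", None)
    if origin is tuple:
        elem = kind.__args__[0]
        return tuple(elem(v.strip()) for v in text.split(",") if v.strip())
    raise DataError(f"unsupported config field type {kind}")


def save_config(cfg: RunConfig, path: str | os.PathLike) -> None:
    """Serialise as flat key = value text; round-trips losslessly."""
    lines = ["# msmdenoise run configuration"]
    for f in fields(cfg):
        lines.append(f"{f.name} = {_format_value(getattr(cfg, f.name))}")
    with open(os.fspath(path), "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_config(path: str | os.PathLike, **overrides) -> RunConfig:
    """Parse a key = value file; keyword overrides win over file values."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise DataError(f"no such config file: {path}")
    known = {f.name: f.type for f in fields(RunConfig)}
    # resolve string annotations (from __future__ import annotations)
    import typing

    hints = typing.get_type_hints(RunConfig)
    values: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise DataError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in known:
                raise DataError(f"{path}:{lineno}: unknown configuration key {key!r}")
            values[key] = _parse_value(val, hints[key])
    values.update(overrides)
    return RunConfig(**values)
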