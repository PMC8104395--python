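"""Result serialization: CSV for curves and lattice fields, HDF5 for circuit
states, PNG heat maps for fields and activity maps."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .analysis import SizeTuningCurve, WeightBreakdown
from .geometry import Lattice, OrientationMap
from .params import POPULATIONS
from .solvers import CircuitState


def orientation_map_frame(omap: OrientationMap) -> pd.DataFrame:
    """Orientation map as a tidy table (m, n, x_deg, y_deg, hc_row, hc_col,
    theta_deg)."""
    lat = omap.lattice
    x, y = lat.meshgrid()
    m, n = np.meshgrid(np.arange(lat.n_side), np.arange(lat.n_side), indexing="ij")
    return pd.DataFrame({
        "m": m.ravel(), "n": n.ravel(),
        "x_deg": x.ravel(), "y_deg": y.ravel(),
        "hc_row": omap.hc_row.ravel(), "hc_col": omap.hc_col.ravel(),
        "theta_deg": omap.theta.ravel(),
    })


def field_frame(field: np.ndarray) -> pd.DataFrame:
    """A lattice field as (m, n, value) rows."""
    m, n = np.meshgrid(*(np.arange(s) for s in field.shape), indexing="ij")
    return pd.DataFrame({"m": m.ravel(), "n": n.ravel(), "value": field.ravel()})


def curve_frame(curve: SizeTuningCurve) -> pd.DataFrame:
    return pd.DataFrame({"R": curve.radii, "response": curve.responses})


def save_curve_csv(curve: SizeTuningCurve, path: str | Path) -> None:
    curve_frame(curve).to_csv(path, index=False, float_format="%.12g")


def breakdown_frame(b: WeightBreakdown) -> pd.DataFrame:
    return pd.DataFrame(
        {"source": list(b.components), "current": list(b.components.values())}
    )


def save_state_h5(state: CircuitState, path: str | Path, **attrs) -> None:
    """Circuit state as one 2D dataset per population plus metadata attrs."""
    with h5py.File(path, "w") as f:
        for pop in POPULATIONS:
            f.create_dataset(pop, data=state.fields[pop])
        f.attrs["residual"] = state.residual
        f.attrs["iterations"] = state.iterations
        f.attrs["nonnegative"] = state.nonnegative
        for k, v in attrs.items():
            f.attrs[k] = v


def load_state_h5(path: str | Path) -> CircuitState:
    with h5py.File(path, "r") as f:
        fields = {pop: f[pop][()] for pop in POPULATIONS}
        return CircuitState(
            fields=fields,
            residual=float(f.attrs["residual"]),
            iterations=int(f.attrs["iterations"]),
            nonnegative=bool(f.attrs["nonnegative"]),
            metadata={k: f.attrs[k] for k in f.attrs},
        )


def save_field_png(field: np.ndarray, path: str | Path, title: str = "",
                   diverging: bool = False) -> None:
    """Lattice field as a raster image (x rightward, y upward)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.2))
    if diverging:
        vmax = float(np.max(np.abs(field))) or 1.0
        im = ax.imshow(field.T, origin="lower", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    else:
        im = ax.imshow(field.T, origin="lower", cmap="viridis")
    fig.colorbar(im, ax=ax)
    ax.set_xlabel("m")
    ax.set_ylabel("n")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)


def save_curves_png(curves: dict[str, SizeTuningCurve], path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(curves), figsize=(3.2 * len(curves), 3), sharex=True)
    for ax, (pop, c) in zip(np.atleast_1d(axes), curves.items()):
        ax.plot(c.radii, c.responses, "o-", ms=3)
        ax.set_title(pop)
        ax.set_xlabel("R (deg)")
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)
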