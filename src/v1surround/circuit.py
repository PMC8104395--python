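"""Assembly of the steady-state system H Theta = b.

At steady state every cortical group's output equals the sum of its inputs
(excitatory minus inhibitory cortical currents, plus LGN current and a small
ambient drive).  Collecting the four population fields over the lattice into a
single vector Theta gives a linear system H Theta = b with H = I - K, where K
holds the signed cortical couplings and b the LGN (orientation-gated for E
targets) and ambient terms.

Two operator representations are provided and must agree to machine precision:

* a matrix-free form in which each projection block is applied as a zero-padded
  2D convolution with cached kernel FFTs (long-range blocks are additionally
  masked by like-orientation-preference), used for full-size lattices; and
* an explicit scipy.sparse matrix, practical for reduced lattices and used by
  the analytic sensitivity path.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.fft as sfft
import scipy.sparse as sp

from .geometry import Lattice, OrientationMap, ORIENTATIONS
from .lgn import orientation_gain_field
from .params import (
    LOCAL_CIRCUIT_RADIUS,
    ModelParameters,
    POPULATIONS,
    ProjectionSpec,
)

_LONG_RANGE_MAX = 1.6  # degrees; p_E and p_I vanish at and beyond this distance


def local_coupling(spec: ProjectionSpec, z, z_star, h: float) -> np.ndarray:
    """Truncated-Gaussian coupling q(z, z*) between two groups (vectorized).

    q = h^2 W / (2 pi sigma^2) exp(-d^2 / (2 sigma^2)) for d <= cutoff radius,
    0 beyond; d = |z - z*|.
    """
    z = np.asarray(z, dtype=float)
    z_star = np.asarray(z_star, dtype=float)
    d2 = np.sum((z - z_star) ** 2, axis=-1)
    amp = h * h * spec.weight / (2 * np.pi * spec.sigma**2)
    val = amp * np.exp(-d2 / (2 * spec.sigma**2))
    return np.where(d2 <= spec.radius**2 * (1 + 1e-12), val, 0.0)


def q0_longrange(params: ModelParameters, target_pop: str, h: float) -> float:
    """Continuity constant: the local 6E->target kernel evaluated at its cutoff
    radius, so that long-range coupling q0 * p(0.15) matches the local circuit
    at the local-circuit boundary."""
    spec = params.projection("6E", target_pop)
    amp = h * h * spec.weight / (2 * np.pi * spec.sigma**2)
    return amp * np.exp(-spec.radius**2 / (2 * spec.sigma**2))


_q0 = q0_longrange


def longrange_coupling(
    z,
    z_star,
    target_pop: str,
    params: ModelParameters,
    omap: OrientationMap,
) -> float:
    """Long-range 6E coupling q0 * p(d) * pi(z, z*) for d > 0.15 (pointwise)."""
    if target_pop not in ("6E", "6I"):
        raise ValueError("long-range projections target 6E or 6I only")
    h = omap.lattice.h
    d = float(np.hypot(z[0] - z_star[0], z[1] - z_star[1]))
    if d <= LOCAL_CIRCUIT_RADIUS or d > _LONG_RANGE_MAX:
        return 0.0
    mi, ni = omap.lattice.index_of(z)
    mj, nj = omap.lattice.index_of(z_star)
    if omap.theta[mi, ni] != omap.theta[mj, nj]:
        return 0.0
    p = params.longrange.p_e(d) if target_pop == "6E" else params.longrange.p_i(d)
    return _q0(params, target_pop, h) * float(p)


def local_kernel_array(spec: ProjectionSpec, h: float) -> np.ndarray:
    """Local kernel sampled on the integer offset grid, shape (2a+1, 2a+1)."""
    a = int(np.floor(spec.radius / h + 1e-9))
    idx = np.arange(-a, a + 1)
    di, dj = np.meshgrid(idx, idx, indexing="ij")
    pts = np.stack([di * h, dj * h], axis=-1)
    return local_coupling(spec, pts, np.zeros(2), h)


def longrange_kernel_array(params: ModelParameters, target_pop: str, h: float) -> np.ndarray:
    """Long-range kernel q0 * p(d) on the offset grid (orientation mask applied
    at operator-application time)."""
    a = int(np.floor(_LONG_RANGE_MAX / h + 1e-9))
    idx = np.arange(-a, a + 1)
    di, dj = np.meshgrid(idx, idx, indexing="ij")
    d = h * np.hypot(di, dj)
    p = params.longrange.p_e(d) if target_pop == "6E" else params.longrange.p_i(d)
    k = _q0(params, target_pop, h) * p
    k[(d <= LOCAL_CIRCUIT_RADIUS) | (d > _LONG_RANGE_MAX)] = 0.0
    return k


# Signed cortical projection blocks of K: (source, target, sign); the sign is
# positive for E sources and negative for I sources (summed-input form).
_BLOCKS: tuple[tuple[str, str, float], ...] = (
    ("4E", "4E", +1.0), ("4I", "4E", -1.0), ("6E", "4E", +1.0),
    ("4E", "4I", +1.0), ("4I", "4I", -1.0), ("6E", "4I", +1.0),
    ("4E", "6E", +1.0), ("6E", "6E", +1.0), ("6I", "6E", -1.0),
    ("4E", "6I", +1.0), ("6E", "6I", +1.0), ("6I", "6I", -1.0),
)


@dataclass
class _KernelFFT:
    half_width: int
    freq: np.ndarray  # cached rfft2 of the zero-padded kernel


class AssembledSystem:
    """The operator H = I - K, the constant vector b, and the index map.

    State vectors are ordered population-major (4E, 4I, 6E, 6I), each
    population field flattened row-major in (m, n).
    """

    def __init__(
        self,
        lattice: Lattice,
        omap: OrientationMap,
        params: ModelParameters,
        lgn_field: np.ndarray,
        theta0: float = 90.0,
        multiplier_fields: dict[tuple[str, str], np.ndarray] | None = None,
    ):
        n = lattice.n_side
        if lgn_field.shape != (n, n):
            raise ValueError(
                f"LGN field shape {lgn_field.shape} does not match lattice ({n}, {n})"
            )
        self.lattice = lattice
        self.omap = omap
        self.params = params
        self.theta0 = theta0
        self.lgn_field = lgn_field
        self.multiplier_fields = multiplier_fields or {}

        self._kernels: dict[tuple[str, str], np.ndarray] = {}
        self._lr_kernels: dict[str, np.ndarray] = {}
        for src, tgt, _sign in _BLOCKS:
            self._kernels[(src, tgt)] = local_kernel_array(params.projection(src, tgt), lattice.h)
        for tgt in ("6E", "6I"):
            self._lr_kernels[tgt] = longrange_kernel_array(params, tgt, lattice.h)
            self._kernels[("LGN", tgt)] = local_kernel_array(
                params.projection("LGN", tgt), lattice.h
            )
        for tgt in ("4E", "4I"):
            self._kernels[("LGN", tgt)] = local_kernel_array(
                params.projection("LGN", tgt), lattice.h
            )

        a_max = max(
            max(k.shape[0] // 2 for k in self._kernels.values()),
            max(k.shape[0] // 2 for k in self._lr_kernels.values()),
        )
        self._a = a_max
        self._pad = sfft.next_fast_len(n + 2 * a_max)
        self._kfft: dict[object, _KernelFFT] = {}
        for key, kern in {**self._kernels, **{("LR", t): k for t, k in self._lr_kernels.items()}}.items():
            self._kfft[key] = self._make_kfft(kern)

        self._ori_masks = {o: (omap.theta == o).astype(float) for o in ORIENTATIONS}
        self._gain_e = orientation_gain_field(omap.theta, theta0)
        self.b = self._build_b()

    # -- index bookkeeping ------------------------------------------------

    @property
    def dimension(self) -> int:
        return 4 * self.lattice.n_points

    def index_of(self, population: str, m: int, n: int) -> int:
        p = POPULATIONS.index(population)
        return p * self.lattice.n_points + m * self.lattice.n_side + n

    def split(self, vec: np.ndarray) -> dict[str, np.ndarray]:
        n = self.lattice.n_side
        npts = self.lattice.n_points
        return {
            pop: vec[i * npts : (i + 1) * npts].reshape(n, n)
            for i, pop in enumerate(POPULATIONS)
        }

    def join(self, fields: dict[str, np.ndarray]) -> np.ndarray:
        return np.concatenate([fields[pop].ravel() for pop in POPULATIONS])

    # -- FFT plumbing ------------------------------------------------------

    def _make_kfft(self, kern: np.ndarray) -> _KernelFFT:
        a = kern.shape[0] // 2
        # embed in a common (2*a_max+1) frame so all blocks share one 'same'
        # slice and can be accumulated in the frequency domain
        A = self._a
        framed = np.zeros((2 * A + 1, 2 * A + 1))
        framed[A - a : A + a + 1, A - a : A + a + 1] = kern
        padded = np.zeros((self._pad, self._pad))
        padded[: 2 * A + 1, : 2 * A + 1] = framed
        return _KernelFFT(half_width=A, freq=sfft.rfft2(padded))

    def _field_fft(self, field: np.ndarray) -> np.ndarray:
        padded = np.zeros((self._pad, self._pad))
        n = self.lattice.n_side
        padded[:n, :n] = field
        return sfft.rfft2(padded)

    def _conv_from_freq(self, freq: np.ndarray) -> np.ndarray:
        n = self.lattice.n_side
        A = self._a
        out = sfft.irfft2(freq, s=(self._pad, self._pad))
        return out[A : A + n, A : A + n]

    def conv_same(self, field: np.ndarray, key) -> np.ndarray:
        """'same'-mode zero-padded convolution of a lattice field with one of
        the assembled kernels."""
        return self._conv_from_freq(self._kfft[key].freq * self._field_fft(field))

    # -- operator and constant vector --------------------------------------

    def _source_variant(self, fields, src, tgt):
        """Source field with this projection's rate-dependent multiplier applied."""
        f = fields[src]
        mult = self.multiplier_fields.get((src, tgt))
        return f if mult is None else f * mult

    def apply_K(self, vec: np.ndarray) -> np.ndarray:
        fields = self.split(vec)
        acc_freq = {pop: np.zeros((self._pad, self._pad // 2 + 1), dtype=complex)
                    for pop in POPULATIONS}

        # one forward FFT per distinct (source field, multiplier) variant;
        # keyed by the projection's multiplier identity, never by object id
        fft_cache: dict[tuple[str, int], np.ndarray] = {}

        def variant_fft(src: str, tgt: str) -> np.ndarray:
            mult = self.multiplier_fields.get((src, tgt))
            key = (src, id(mult) if mult is not None else 0)
            if key not in fft_cache:
                f = fields[src] if mult is None else fields[src] * mult
                fft_cache[key] = self._field_fft(f)
            return fft_cache[key]

        for src, tgt, sign in _BLOCKS:
            acc_freq[tgt] += sign * self._kfft[(src, tgt)].freq * variant_fft(src, tgt)

        out = {pop: self._conv_from_freq(acc_freq[pop]) for pop in POPULATIONS}

        # long-range 6E projections, gated by like orientation preference;
        # the rate-dependent multiplier (if any) acts per projection, so the
        # 6E->6E multiplier does not touch the 6E->6I long-range branch
        for tgt in ("6E", "6I"):
            src_lr = self._source_variant(fields, "6E", tgt)
            kf = self._kfft[("LR", tgt)].freq
            for o, mask in self._ori_masks.items():
                res = self._conv_from_freq(kf * self._field_fft(mask * src_lr))
                out[tgt] += mask * res
        return self.join(out)

    def matvec(self, vec: np.ndarray) -> np.ndarray:
        """H v = v - K v."""
        return vec - self.apply_K(vec)

    def _build_b(self) -> np.ndarray:
        fields = {}
        for pop in POPULATIONS:
            lgn_term = self.conv_same(self.lgn_field, ("LGN", pop))
            if pop.endswith("E"):
                lgn_term = lgn_term * self._gain_e
            fields[pop] = lgn_term + self.params.ambient[pop]
        return self.join(fields)

    def with_multiplier_fields(
        self, multiplier_fields: dict[tuple[str, str], np.ndarray]
    ) -> "AssembledSystem":
        """Cheap copy sharing the cached kernel FFTs but with new
        rate-dependent multiplier fields (used by the fixed-point solver)."""
        import copy

        clone = copy.copy(self)
        clone.multiplier_fields = multiplier_fields
        return clone

    # -- explicit sparse path ----------------------------------------------

    def to_sparse(self) -> sp.csr_matrix:
        """Explicit H as a sparse matrix (intended for reduced lattices)."""
        n = self.lattice.n_side
        npts = self.lattice.n_points
        rows, cols, vals = [], [], []

        def add_block(kern, src, tgt, sign, mask_orientation, mult):
            a = kern.shape[0] // 2
            p_src = POPULATIONS.index(src)
            p_tgt = POPULATIONS.index(tgt)
            nz = np.argwhere(kern != 0.0)
            for di, dj in nz - a:
                w = kern[di + a, dj + a]
                # target (m, n), source (m+di, n+dj)
                m_lo, m_hi = max(0, -di), min(n, n - di)
                n_lo, n_hi = max(0, -dj), min(n, n - dj)
                if m_lo >= m_hi or n_lo >= n_hi:
                    continue
                tm, tn = np.meshgrid(
                    np.arange(m_lo, m_hi), np.arange(n_lo, n_hi), indexing="ij"
                )
                sm, sn = tm + di, tn + dj
                keep = np.ones(tm.shape, dtype=bool)
                if mask_orientation:
                    keep = self.omap.theta[tm, tn] == self.omap.theta[sm, sn]
                scale = np.full(tm.shape, w)
                if mult is not None:
                    scale = scale * mult[sm, sn]
                tm, tn, sm, sn, scale = (
                    arr[keep] for arr in (tm, tn, sm, sn, scale)
                )
                rows.append(p_tgt * npts + tm * n + tn)
                cols.append(p_src * npts + sm * n + sn)
                vals.append(sign * scale)

        for src, tgt, sign in _BLOCKS:
            add_block(
                self._kernels[(src, tgt)], src, tgt, sign,
                mask_orientation=False,
                mult=self.multiplier_fields.get((src, tgt)),
            )
        for tgt in ("6E", "6I"):
            add_block(
                self._lr_kernels[tgt], "6E", tgt, +1.0,
                mask_orientation=True,
                mult=self.multiplier_fields.get(("6E", tgt)),
            )

        if rows:
            K = sp.coo_matrix(
                (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                shape=(self.dimension, self.dimension),
            ).tocsr()
        else:  # fully decoupled circuit (all weights zero)
            K = sp.csr_matrix((self.dimension, self.dimension))
        return (sp.identity(self.dimension, format="csr") - K).tocsr()

    # -- weight analysis support --------------------------------------------

    def input_components(self, fields: dict[str, np.ndarray], population: str,
                         location: tuple[int, int]) -> dict[str, float]:
        """Signed input current to one target group, broken down by source
        class (LGN, 4E, 4I, 6E, 6I, Ambient)."""
        m0, n0 = location
        n = self.lattice.n_side
        comps = {src: 0.0 for src in ("LGN", "4E", "4I", "6E", "6I")}

        def window(field, a):
            padded = np.zeros((n + 2 * a, n + 2 * a))
            padded[a : a + n, a : a + n] = field
            return padded[m0 : m0 + 2 * a + 1, n0 : n0 + 2 * a + 1]

        for src, tgt, sign in _BLOCKS:
            if tgt != population:
                continue
            kern = self._kernels[(src, tgt)]
            a = kern.shape[0] // 2
            f = self._source_variant(fields, src, tgt)
            comps[src] += sign * float(np.sum(kern * window(f, a)))
        if population in ("6E", "6I"):
            kern = self._lr_kernels[population]
            a = kern.shape[0] // 2
            f = self._source_variant(fields, "6E", population)
            same = window(
                (self.omap.theta == self.omap.theta[m0, n0]).astype(float), a
            )
            comps["6E"] += float(np.sum(kern * same * window(f, a)))

        lgn_term = float(
            np.sum(self._kernels[("LGN", population)]
                   * window(self.lgn_field, self._kernels[("LGN", population)].shape[0] // 2))
        )
        if population.endswith("E"):
            lgn_term *= self._gain_e[m0, n0]
        comps["LGN"] = lgn_term
        comps["Ambient"] = self.params.ambient[population]
        return comps


def assemble_system(
    lattice: Lattice,
    omap: OrientationMap,
    params: ModelParameters,
    lgn_field: np.ndarray,
    theta0: float = 90.0,
    multiplier_fields: dict[tuple[str, str], np.ndarray] | None = None,
) -> AssembledSystem:
    """Assemble H and b for one stimulus condition."""
    return AssembledSystem(lattice, omap, params, lgn_field, theta0, multiplier_fields)
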