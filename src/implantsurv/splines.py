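"""Restricted cubic spline basis on log time.

The basis models the log cumulative hazard as a smooth function of
``x = ln(t)``.  With ``df`` degrees of freedom there are ``df - 1`` internal
knots placed at centiles ``100*j/df`` of the uncensored log event times, and
boundary knots at the minimum and maximum uncensored log event time.  The
derived columns are

    z_1 = x
    z_j = (x - k_j)+^3 - phi_j (x - k_min)+^3 - (1 - phi_j)(x - k_max)+^3

for internal knots ``k_j``, with ``phi_j = (k_max - k_j) / (k_max - k_min)``
and ``(u)+^3 = max(0, u)^3``.  The restriction forces the fitted curve to be
linear beyond the boundary knots with continuous 0th/1st/2nd derivatives
everywhere.  ``df = 1`` has no internal knots and the basis reduces to
``{1, x}``: on the log-cumulative-hazard scale that is exactly the Weibull
model.

Derived columns are highly collinear, so the full spline design (including
the intercept) can be orthogonalised by Gram-Schmidt over a sample of
``x`` values; the linear transform is stored so fitted predictions are
invariant to the choice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

MAX_DF = 9  # maximum number of basis terms supported


class SplineError(ValueError):
    pass


@dataclass(frozen=True)
class SplineBasis:
    """Restricted cubic spline basis of ``df`` terms on the log-time scale.

    ``ortho_transform`` is an invertible ``(df+1, df+1)`` matrix applied on
    the right of the raw design ``[1, z_1, ..., z_df]``; identity when
    orthogonalisation is disabled.
    """

    df: int
    internal_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]
    ortho_transform: np.ndarray | None = None

    def __post_init__(self):
        if self.df < 1 or self.df > MAX_DF:
            raise SplineError(f"df must be in [1, {MAX_DF}], got {self.df}")
        if len(self.internal_knots) != self.df - 1:
            raise SplineError(
                f"df={self.df} requires {self.df - 1} internal knots, "
                f"got {len(self.internal_knots)}"
            )
        lo, hi = self.boundary_knots
        if not lo < hi:
            raise SplineError("boundary knots must satisfy k_min < k_max")
        for k in self.internal_knots:
            if not (lo < k < hi):
                raise SplineError(
                    f"internal knot {k} not strictly inside boundary ({lo}, {hi})"
                )
        if self.ortho_transform is not None:
            T = np.asarray(self.ortho_transform, float)
            if T.shape != (self.df + 1, self.df + 1):
                raise SplineError("ortho_transform has wrong shape")

    @property
    def n_columns(self) -> int:
        """Columns of the full design including the intercept term."""
        return self.df + 1

    # -- raw basis -----------------------------------------------------------
    def _raw(self, x: np.ndarray) -> np.ndarray:
        """Design ``[1, z_1, ..., z_df]`` before orthogonalisation."""
        x = np.atleast_1d(np.asarray(x, float))
        kmin, kmax = self.boundary_knots
        cols = [np.ones_like(x), x]
        for kj in self.internal_knots:
            phi = (kmax - kj) / (kmax - kmin)
            z = (
                np.maximum(0.0, x - kj) ** 3
                - phi * np.maximum(0.0, x - kmin) ** 3
                - (1.0 - phi) * np.maximum(0.0, x - kmax) ** 3
            )
            cols.append(z)
        return np.column_stack(cols)

    def _raw_deriv(self, x: np.ndarray) -> np.ndarray:
        """d/dx of the raw design (intercept column derivative is 0)."""
        x = np.atleast_1d(np.asarray(x, float))
        kmin, kmax = self.boundary_knots
        cols = [np.zeros_like(x), np.ones_like(x)]
        for kj in self.internal_knots:
            phi = (kmax - kj) / (kmax - kmin)
            dz = 3.0 * (
                np.maximum(0.0, x - kj) ** 2
                - phi * np.maximum(0.0, x - kmin) ** 2
                - (1.0 - phi) * np.maximum(0.0, x - kmax) ** 2
            )
            cols.append(dz)
        return np.column_stack(cols)

    # -- public evaluation ---------------------------------------------------
    def design(self, x) -> np.ndarray:
        """Full (n, df+1) design at log-times ``x``, transform applied."""
        A = self._raw(x)
        if self.ortho_transform is not None:
            A = A @ self.ortho_transform
        return A

    def design_deriv(self, x) -> np.ndarray:
        """d/dx of :meth:`design`; consistent with the stored transform."""
        A = self._raw_deriv(x)
        if self.ortho_transform is not None:
            A = A @ self.ortho_transform
        return A

    def evaluate(self, x) -> np.ndarray:
        """Derived basis columns z_1..z_df (no intercept), transform applied.

        With orthogonalisation on, the returned columns are the transformed
        non-intercept columns of the full design.
        """
        return self.design(x)[:, 1:]

    def derivative(self, x) -> np.ndarray:
        """Analytic d z_j / dx for the columns of :meth:`evaluate`."""
        return self.design_deriv(x)[:, 1:]

    # -- serialisation -------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "df": self.df,
                "internal_knots": list(self.internal_knots),
                "boundary_knots": list(self.boundary_knots),
                "ortho_transform": (
                    None
                    if self.ortho_transform is None
                    else np.asarray(self.ortho_transform).tolist()
                ),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SplineBasis":
        d = json.loads(text)
        T = d["ortho_transform"]
        return cls(
            df=int(d["df"]),
            internal_knots=tuple(d["internal_knots"]),
            boundary_knots=tuple(d["boundary_knots"]),
            ortho_transform=None if T is None else np.asarray(T, float),
        )


def place_knots(df: int, uncensored_log_times: np.ndarray) -> SplineBasis:
    """Centile-based knot placement on uncensored log event times.

    Internal knots sit at centiles ``100*j/df`` (j = 1..df-1) of the
    uncensored log event times; boundary knots at their minimum and maximum.
    ``df = 1`` yields no internal knots (the Weibull special case).
    """
    if df < 1 or df > MAX_DF:
        raise SplineError(f"df must be in [1, {MAX_DF}], got {df}")
    x = np.sort(np.asarray(uncensored_log_times, float))
    if x.size < 2 or x[0] == x[-1]:
        raise SplineError("need at least 2 distinct uncensored times")
    if df >= 2:
        centiles = internal_knot_centiles(df)
        internal = tuple(np.quantile(x, centiles / 100.0, method="linear"))
        if len(set(internal)) != len(internal) or not all(
            x[0] < k < x[-1] for k in internal
        ):
            raise SplineError(
                f"too few distinct uncensored times for df={df} knot placement"
            )
    else:
        internal = ()
    return SplineBasis(df=df, internal_knots=internal, boundary_knots=(x[0], x[-1]))


def internal_knot_centiles(df: int) -> np.ndarray:
    """Centile positions 100*j/df, j = 1..df-1 (e.g. df=4 -> 25, 50, 75)."""
    if df < 1:
        raise SplineError("df must be >= 1")
    return 100.0 * np.arange(1, df) / df


def orthogonalize(basis: SplineBasis, sample_x: np.ndarray) -> SplineBasis:
    """Gram-Schmidt orthogonalisation of the full design over ``sample_x``.

    Returns a new basis whose design columns are orthonormal (up to a common
    scale) over the sample points.  Predictions from any fit are invariant
    because the transform is stored and invertible.
    """
    sample_x = np.asarray(sample_x, float)
    if np.unique(sample_x).size < basis.df + 1:
        raise SplineError("need at least df+1 distinct sample points")
    A = basis._raw(sample_x)
    # Thin QR == Gram-Schmidt on the columns; R^-1 maps raw -> orthonormal.
    q, r = np.linalg.qr(A)
    if np.min(np.abs(np.diag(r))) < 1e-12 * np.max(np.abs(np.diag(r))):
        raise SplineError("rank-deficient spline design; cannot orthogonalise")
    # Fix signs so the transform is deterministic.
    signs = np.sign(np.diag(r))
    r = r * signs[:, None]
    T = np.linalg.inv(r) * np.sqrt(len(sample_x))
    return replace(basis, ortho_transform=T)
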