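"""Partial least squares discriminant analysis (PLS-DA) via NIPALS.

PLS-DA regresses a one-hot encoding of class membership on an autoscaled
feature block and reads group separation off the X-block latent
variables. The decomposition here is the classical two-block NIPALS
iteration with regression deflation of both blocks:

    u <- a Y column;  w = X'u / u'u, normalised;  t = X w;
    q = Y't / t't;    u = Y q / q'q;   iterate to convergence of t,
    then p = X't / t't,  X <- X - t p',  Y <- Y - t q'.

Score vectors from successive components are mutually orthogonal. The
fit is deterministic: the starting u is the Y column with the largest
residual variance, and each weight vector's sign is fixed so its
largest-magnitude entry is positive.

The API follows the model/results convention: build a :class:`PLSDA`
from data, call :meth:`PLSDA.fit`, and read estimates and diagnostics
off the returned :class:`PLSDAResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bifidopanel.stats import autoscale

__all__ = ["PLSDA", "PLSDAResults"]


class ConvergenceError(RuntimeError):
    """NIPALS failed to converge; carries the iteration count."""

    def __init__(self, component: int, iterations: int):
        self.component = component
        self.iterations = iterations
        super().__init__(
            f"NIPALS did not converge for component {component + 1} "
            f"after {iterations} iterations"
        )


class PLSDA:
    """Two-class-or-more PLS-DA model on an autoscaled feature block.

    Parameters
    ----------
    X : array-like or DataFrame, samples x variables
        Feature block; every variable must have positive variance.
    labels : sequence
        Class label per sample; at least two distinct classes.
    n_components : int
        Number of latent variables (default 2).
    scale : bool
        Autoscale X to zero mean, unit variance (default True; the
        class indicator block is always autoscaled).
    tol, max_iter :
        NIPALS convergence tolerance on the score vector (default
        1e-10) and iteration cap (default 2000; at this tolerance the
        power-iteration inner loop can need several hundred rounds when
        two discriminating directions are near-degenerate).
    """

    def __init__(
        self,
        X,
        labels,
        n_components: int = 2,
        *,
        scale: bool = True,
        tol: float = 1e-10,
        max_iter: int = 2000,
    ):
        if isinstance(X, pd.DataFrame):
            self.var_names = list(X.columns)
            Xdf = X.astype(float)
        else:
            X = np.asarray(X, dtype=float)
            self.var_names = [f"x{j}" for j in range(X.shape[1])]
            Xdf = pd.DataFrame(X, columns=self.var_names)
        self.labels = np.asarray(labels)
        if len(self.labels) != len(Xdf):
            raise ValueError(
                f"labels length {len(self.labels)} != sample count {len(Xdf)}"
            )
        self.classes = [str(c) for c in pd.unique(self.labels)]
        if len(self.classes) < 2:
            raise ValueError("PLS-DA requires at least two classes")
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        self.n_components = int(n_components)
        self.scale = scale
        self.tol = tol
        self.max_iter = max_iter

        if scale:
            scaled, means, scales = autoscale(Xdf)
            self._X0 = scaled.to_numpy()
            self.means = means
            self.scales = scales
        else:
            self.means = Xdf.mean()
            self.scales = pd.Series(1.0, index=Xdf.columns)
            self._X0 = (Xdf - self.means).to_numpy()

        rank = np.linalg.matrix_rank(self._X0)
        if self.n_components > rank:
            raise ValueError(
                f"n_components={self.n_components} exceeds the rank "
                f"({rank}) of the autoscaled feature block"
            )
        # autoscaled one-hot class indicator block: scaling each class
        # column to unit variance gives every class equal pull on the
        # latent variables even when group sizes are unbalanced
        onehot = np.stack(
            [(self.labels == c).astype(float) for c in pd.unique(self.labels)], axis=1
        )
        self._Y0 = (onehot - onehot.mean(axis=0)) / onehot.std(axis=0, ddof=1)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_col: str, feature_cols: list[str] | None = None, **kw
    ) -> "PLSDA":
        """Build a model from a tidy table with a label column."""
        if feature_cols is None:
            feature_cols = [c for c in df.columns if c != label_col]
        return cls(df[feature_cols], df[label_col].to_numpy(), **kw)

    def fit(self) -> "PLSDAResults":
        """Run NIPALS and return the results object."""
        X = self._X0.copy()
        Y = self._Y0.copy()
        n, k = X.shape
        A = self.n_components
        W = np.zeros((k, A))
        P = np.zeros((k, A))
        T = np.zeros((n, A))
        U = np.zeros((n, A))
        Q = np.zeros((Y.shape[1], A))
        iterations = []
        total_ssx = float((self._X0 ** 2).sum())
        x_var = np.zeros(A)

        for a in range(A):
            u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
            t_old = np.zeros(n)
            for it in range(1, self.max_iter + 1):
                w = X.T @ u / (u @ u)
                w /= np.linalg.norm(w)
                t = X @ w
                q = Y.T @ t / (t @ t)
                denom = q @ q
                if denom == 0:  # Y residual exhausted
                    break
                u = Y @ q / denom
                if np.linalg.norm(t - t_old) < self.tol * max(np.linalg.norm(t), 1.0):
                    break
                t_old = t
            else:
                raise ConvergenceError(a, self.max_iter)
            iterations.append(it)
            # sign convention: dominant weight entry positive
            if w[int(np.argmax(np.abs(w)))] < 0:
                w, t, q, u = -w, -t, -q, -u
            p = X.T @ t / (t @ t)
            X = X - np.outer(t, p)
            Y = Y - np.outer(t, q)
            W[:, a], P[:, a], T[:, a], U[:, a], Q[:, a] = w, p, t, u, q
            x_var[a] = float((t @ t) * (p @ p)) / total_ssx

        idx = self.var_names
        comps = [f"LV{a + 1}" for a in range(A)]
        return PLSDAResults(
            model=self,
            x_scores=pd.DataFrame(T, columns=comps),
            x_weights=pd.DataFrame(W, index=idx, columns=comps),
            x_loadings=pd.DataFrame(P, index=idx, columns=comps),
            y_loadings=pd.DataFrame(Q, index=self.classes, columns=comps),
            y_scores=pd.DataFrame(U, columns=comps),
            x_residual=X,
            explained_x_variance=pd.Series(x_var, index=comps),
            n_iterations=tuple(iterations),
        )


@dataclass
class PLSDAResults:
    """Fitted PLS-DA decomposition.

    ``x_scores`` (samples x LVs) carry the sample ordination,
    ``x_loadings``/``x_weights`` (variables x LVs) the variable
    contributions, ``y_loadings`` (classes x LVs) the class directions.
    ``explained_x_variance`` is the fraction of autoscaled X sum of
    squares captured by each LV.
    """

    model: PLSDA
    x_scores: pd.DataFrame
    x_weights: pd.DataFrame
    x_loadings: pd.DataFrame
    y_loadings: pd.DataFrame
    y_scores: pd.DataFrame
    x_residual: np.ndarray
    explained_x_variance: pd.Series
    n_iterations: tuple[int, ...] = field(default=())

    @property
    def classes(self) -> list[str]:
        return self.model.classes

    @property
    def labels(self) -> np.ndarray:
        return self.model.labels

    def loading_ranking(self, component: int = 0) -> pd.Series:
        """Variables ordered by |loading| on one LV, largest first."""
        col = self.x_loadings.iloc[:, component]
        return col.reindex(col.abs().sort_values(ascending=False).index)

    def summary(self) -> str:
        lines = [
            "PLS-DA (NIPALS)",
            f"  samples: {len(self.x_scores)}   variables: {len(self.x_loadings)}"
            f"   classes: {', '.join(self.classes)}",
            f"  latent variables: {self.model.n_components}"
            f"   iterations: {list(self.n_iterations)}",
            "  explained X variance: "
            + ", ".join(
                f"{c} {100 * v:.1f}%" for c, v in self.explained_x_variance.items()
            ),
            "  top |LV1| loadings:",
        ]
        for name, val in self.loading_ranking(0).head(5).items():
            lines.append(f"    {name:<28s} {val:+.3f}")
        return "\n".join(lines)

    def plot_scores(self, ax=None, components=(0, 1)):
        """Scatter the samples on two LVs, coloured by class."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        i, j = components
        labels = self.labels.astype(str)
        for c in self.classes:
            mask = labels == c
            ax.scatter(
                self.x_scores.iloc[mask, i], self.x_scores.iloc[mask, j], label=str(c), s=20
            )
        ax.axhline(0, lw=0.5, color="grey")
        ax.axvline(0, lw=0.5, color="grey")
        ax.set_xlabel(self.x_scores.columns[i])
        ax.set_ylabel(self.x_scores.columns[j])
        ax.legend(title="group")
        return ax
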