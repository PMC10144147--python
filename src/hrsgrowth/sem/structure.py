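"""Linear latent-variable moment structure with a free/fixed/equality map.

A model is five template matrices — manifest intercepts ``nu``, loadings
``lam``, latent means ``alpha``, latent covariance ``psi`` and manifest
residual covariance ``theta`` — whose cells are either fixed floats or
string parameter labels.  The same label in several cells is an equality
constraint.  Implied moments are ``mu = nu + lam @ alpha`` and
``Sigma = lam @ psi @ lam.T + theta``.

Two parameterisations coexist:

* the *natural* one — one value per distinct label (variances as variances,
  covariances as covariances) — used for reporting and inference; and
* the *internal* unconstrained one used by the optimizer — labels named in
  ``positive`` are carried as log-SDs, and when ``psi_cholesky`` is set the
  whole (fully free) latent covariance is carried as its log-Cholesky
  factor.
"""

from __future__ import annotations

import json

import numpy as np

__all__ = ["MomentStructure"]

_MATRICES = ("nu", "lam", "alpha", "theta", "psi")
_SYMMETRIC = ("theta", "psi")


def _as_object(mat, shape):
    arr = np.empty(shape, dtype=object)
    mat = np.asarray(mat, dtype=object).reshape(shape)
    arr[...] = mat
    return arr


class MomentStructure:
    def __init__(self, manifest_names, latent_names, nu, lam, alpha, psi, theta,
                 psi_cholesky: bool = False, positive=(), start=None):
        self.manifest_names = list(manifest_names)
        self.latent_names = list(latent_names)
        m, k = len(self.manifest_names), len(self.latent_names)
        self.n_manifest, self.n_latent = m, k
        self.templates = {
            "nu": _as_object(nu, (m,)),
            "lam": _as_object(lam, (m, k)),
            "alpha": _as_object(alpha, (k,)),
            "psi": _as_object(psi, (k, k)),
            "theta": _as_object(theta, (m, m)),
        }
        for name in _SYMMETRIC:
            t = self.templates[name]
            for i in range(t.shape[0]):
                for j in range(i + 1, t.shape[1]):
                    t[i, j] = t[j, i]
        self.psi_cholesky = bool(psi_cholesky)
        if self.psi_cholesky:
            t = self.templates["psi"]
            for i in range(k):
                for j in range(i + 1):
                    if not isinstance(t[i, j], str):
                        raise ValueError("psi_cholesky requires a fully free psi")
        self.positive = set(positive)
        self._build_map()
        self._start = dict(start or {})

    # ------------------------------------------------------------------
    def _build_map(self):
        self.base = {}
        self.assign: dict[str, list] = {}
        order: list[str] = []
        for name in _MATRICES:
            t = self.templates[name]
            base = np.zeros(t.shape, dtype=float)
            it = np.ndindex(t.shape)
            for ix in it:
                if name in _SYMMETRIC and ix[1] > ix[0]:
                    continue
                cell = t[ix]
                if isinstance(cell, str):
                    if cell not in self.assign:
                        self.assign[cell] = []
                        order.append(cell)
                    self.assign[cell].append((name, ix))
                else:
                    base[ix] = float(cell)
                    if name in _SYMMETRIC:
                        base[ix[::-1]] = float(cell)
            self.base[name] = base
        self.param_names = order
        self.n_free = len(order)
        if self.psi_cholesky:
            k = self.n_latent
            self._psi_labels = [self.templates["psi"][i, j] for i in range(k) for j in range(i + 1)]
            psi_set = set(self._psi_labels)
            self._nonpsi = [p for p in self.param_names if p not in psi_set]
        else:
            self._psi_labels = []
            self._nonpsi = list(self.param_names)
        self._index = {p: i for i, p in enumerate(self.param_names)}

    # ------------------------------------------------------------------
    def param_dict(self, theta) -> dict:
        return dict(zip(self.param_names, np.asarray(theta, dtype=float)))

    def fill(self, theta):
        """Natural parameter vector -> (nu, lam, alpha, psi, theta) matrices."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_free,):
            raise ValueError(f"expected {self.n_free} parameters, got {theta.shape}")
        mats = {name: self.base[name].copy() for name in _MATRICES}
        for label, value in zip(self.param_names, theta):
            for name, ix in self.assign[label]:
                mats[name][ix] = value
                if name in _SYMMETRIC and ix[0] != ix[1]:
                    mats[name][ix[::-1]] = value
        return mats["nu"], mats["lam"], mats["alpha"], mats["psi"], mats["theta"]

    def implied_moments(self, theta):
        """mu = nu + lam @ alpha, Sigma = lam @ psi @ lam.T + theta."""
        nu, lam, alpha, psi, th = self.fill(theta)
        mu = nu + lam @ alpha
        sigma = lam @ psi @ lam.T + th
        return mu, sigma

    # ------------------------------------------------------------------
    # internal (unconstrained) <-> natural
    def to_internal(self, theta_nat):
        d = self.param_dict(theta_nat)
        out = []
        for p in self._nonpsi:
            v = d[p]
            if p in self.positive:
                if v <= 0:
                    raise ValueError(f"start for positive parameter {p} must be > 0")
                out.append(0.5 * np.log(v))
            else:
                out.append(v)
        if self.psi_cholesky:
            k = self.n_latent
            psi = np.zeros((k, k))
            t = self.templates["psi"]
            for i in range(k):
                for j in range(i + 1):
                    psi[i, j] = psi[j, i] = d[t[i, j]]
            L = np.linalg.cholesky(psi + 1e-12 * np.eye(k))
            for i in range(k):
                for j in range(i + 1):
                    out.append(np.log(L[i, i]) if i == j else L[i, j])
        return np.asarray(out, dtype=float)

    def to_natural(self, theta_int):
        theta_int = np.asarray(theta_int, dtype=float)
        d = {}
        pos = 0
        for p in self._nonpsi:
            v = theta_int[pos]
            d[p] = float(np.exp(2 * v)) if p in self.positive else float(v)
            pos += 1
        if self.psi_cholesky:
            L = self._chol_from_internal(theta_int[pos:])
            psi = L @ L.T
            t = self.templates["psi"]
            for i in range(self.n_latent):
                for j in range(i + 1):
                    d[t[i, j]] = psi[i, j]
        return np.asarray([d[p] for p in self.param_names], dtype=float)

    def _chol_from_internal(self, vals):
        k = self.n_latent
        L = np.zeros((k, k))
        pos = 0
        for i in range(k):
            for j in range(i + 1):
                L[i, j] = np.exp(vals[pos]) if i == j else vals[pos]
                pos += 1
        return L

    @property
    def n_internal(self):
        extra = self.n_latent * (self.n_latent + 1) // 2 if self.psi_cholesky else 0
        return len(self._nonpsi) + extra

    # ------------------------------------------------------------------
    def moment_derivatives(self, theta, internal: bool = False):
        """Per-parameter derivative of (mu, Sigma).

        Returns ``(mu, Sigma, [(dmu_k, dSigma_k), ...])`` with one entry per
        natural parameter (``internal=False``) or per unconstrained internal
        parameter (``internal=True``), evaluated at ``theta`` given in the
        corresponding parameterisation.
        """
        theta_nat = self.to_natural(theta) if internal else np.asarray(theta, dtype=float)
        nu, lam, alpha, psi, th = self.fill(theta_nat)
        mu = nu + lam @ alpha
        sigma = lam @ psi @ lam.T + th
        m, k = self.n_manifest, self.n_latent
        d = self.param_dict(theta_nat)

        def cell_derivs(label, scale=1.0):
            dnu = np.zeros(m)
            dlam = np.zeros((m, k))
            dalpha = np.zeros(k)
            dpsi = np.zeros((k, k))
            dth = np.zeros((m, m))
            tgt = {"nu": dnu, "lam": dlam, "alpha": dalpha, "psi": dpsi, "theta": dth}
            for name, ix in self.assign[label]:
                tgt[name][ix] = scale
                if name in _SYMMETRIC and ix[0] != ix[1]:
                    tgt[name][ix[::-1]] = scale
            dmu = dnu + dlam @ alpha + lam @ dalpha
            dsig = dlam @ (psi @ lam.T) + (lam @ psi) @ dlam.T + lam @ dpsi @ lam.T + dth
            return dmu, dsig

        out = []
        if not internal:
            for p in self.param_names:
                out.append(cell_derivs(p))
            return mu, sigma, out

        pos = 0
        for p in self._nonpsi:
            scale = 2.0 * d[p] if p in self.positive else 1.0  # d(e^{2u})/du = 2v
            out.append(cell_derivs(p, scale))
            pos += 1
        if self.psi_cholesky:
            theta_int = np.asarray(theta, dtype=float)
            L = self._chol_from_internal(theta_int[pos:])
            for i in range(k):
                for j in range(i + 1):
                    E = np.zeros((k, k))
                    E[i, j] = L[i, i] if i == j else 1.0  # log-diagonal chain rule
                    dpsi = E @ L.T + L @ E.T
                    dsig = lam @ dpsi @ lam.T
                    out.append((np.zeros(m), dsig))
        return mu, sigma, out

    # ------------------------------------------------------------------
    def default_start(self, col_stats=None) -> np.ndarray:
        """Heuristic natural start values from (column means, column variances)."""
        col_mean = col_var = None
        if col_stats is not None:
            col_mean, col_var = (np.asarray(a, dtype=float) for a in col_stats)
        start = {}
        for p in self.param_names:
            if p in self._start:
                start[p] = self._start[p]
                continue
            name, ix = self.assign[p][0]
            if name == "nu":
                start[p] = col_mean[ix[0]] if col_mean is not None else 0.0
            elif name == "lam":
                start[p] = 0.5
            elif name == "alpha":
                start[p] = 0.0
            elif name == "theta":
                if ix[0] == ix[1]:
                    start[p] = 0.5 * col_var[ix[0]] if col_var is not None else 0.5
                    start[p] = max(start[p], 1e-3)
                else:
                    start[p] = 0.0
            else:  # psi
                start[p] = 1.0 if ix[0] == ix[1] else 0.0
        return np.asarray([start[p] for p in self.param_names], dtype=float)

    def set_start(self, **values):
        self._start.update(values)

    # ------------------------------------------------------------------
    def to_json(self) -> str:
        def enc(t):
            conv = lambda c: c if isinstance(c, str) else float(c)
            return [[conv(c) for c in row] for row in np.atleast_2d(t)]

        return json.dumps({
            "manifest_names": self.manifest_names,
            "latent_names": self.latent_names,
            "nu": enc(self.templates["nu"]),
            "lam": enc(self.templates["lam"]),
            "alpha": enc(self.templates["alpha"]),
            "psi": enc(self.templates["psi"]),
            "theta": enc(self.templates["theta"]),
            "psi_cholesky": self.psi_cholesky,
            "positive": sorted(self.positive),
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MomentStructure":
        obj = json.loads(text)
        def squeeze(x, one_d):
            return [r[0] for r in x] if one_d and len(x[0]) == 1 else (x[0] if one_d else x)
        m, k = len(obj["manifest_names"]), len(obj["latent_names"])
        nu = np.asarray(obj["nu"], dtype=object).reshape(m)
        alpha = np.asarray(obj["alpha"], dtype=object).reshape(k)
        return cls(obj["manifest_names"], obj["latent_names"], nu, obj["lam"],
                   alpha, obj["psi"], obj["theta"], obj["psi_cholesky"],
                   obj["positive"])
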