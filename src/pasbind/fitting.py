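"""Kd estimation from replicated fluorescence-anisotropy titration curves.

Anisotropy reports the fraction of labeled probe bound to the (large, slowly
tumbling) receptor.  Two assay designs are supported:

* **direct** — the receptor is titrated against a fixed labeled probe; the
  bound fraction follows the depletion-aware quadratic isotherm and the fit
  estimates the probe Kd;
* **competition** — an unlabeled competitor is titrated against fixed probe
  and receptor; the bound probe fraction follows the exact ternary
  equilibrium, and the fit estimates the competitor Kd given the probe Kd
  from a prior direct fit.

Fits are nonlinear least squares over (log10 Kd, r_free, r_bound) with the
intensity-change factor Q fixed (default 1).  Replicates are pooled as
individual points, never averaged first, so the residual bootstrap sees the
full error structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .equilibrium import fraction_bound_direct, free_receptor_competitive

__all__ = [
    "TitrationPoint",
    "TitrationCurve",
    "BindingFitResult",
    "predict_anisotropy",
    "fit_direct",
    "fit_competition",
    "fit_curve",
    "estimate_uncertainty",
    "read_curve",
    "write_curve",
    "fit_results_to_frame",
    "write_fit_results",
]

_RSS_TOL = 1e-10  # relative rss tie tolerance between multi-start solutions
_PLATEAU_DEPRESSION = 0.9  # competition curves that stay above this fraction
# of the upper plateau never resolve the Kd (lower bound only)


@dataclass(frozen=True)
class TitrationPoint:
    """One anisotropy reading: titrant concentration (nM), signal, replicate."""

    titrant: float
    anisotropy: float
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.titrant) or self.titrant < 0:
            raise ValueError(f"titrant must be finite and >= 0, got {self.titrant!r}")
        if not np.isfinite(self.anisotropy):
            raise ValueError("anisotropy must be finite")


@dataclass
class TitrationCurve:
    """A replicated titration series with its fixed assay concentrations.

    For ``assay_kind='direct'`` the titrant is the receptor; for
    ``'competition'`` it is the unlabeled competitor, and ``receptor_total``
    and ``kd_probe`` (both nM) must be given.
    """

    assay_kind: str
    probe_total: float
    points: list[TitrationPoint]
    receptor_total: float | None = None
    kd_probe: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.assay_kind not in ("direct", "competition"):
            raise ValueError(f"assay_kind must be direct|competition, got {self.assay_kind!r}")
        if self.assay_kind == "competition":
            if self.receptor_total is None or self.kd_probe is None:
                raise ValueError("competition curves require receptor_total and kd_probe")
        if len({p.titrant for p in self.points}) < 6:
            raise ValueError("need >= 6 distinct titrant concentrations")

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(titrant, anisotropy, replicate) sorted by (titrant, anisotropy).

        Sorting by concentration and signal — never by the replicate label —
        makes every downstream fit invariant to point order and to replicate
        relabeling.
        """
        t = np.array([p.titrant for p in self.points])
        a = np.array([p.anisotropy for p in self.points])
        rep = np.array([p.replicate_id for p in self.points])
        order = np.lexsort((rep, a, t))
        return t[order], a[order], rep[order]


@dataclass
class BindingFitResult:
    """Estimated Kd with signal endpoints, diagnostics and flags."""

    kd_hat: float
    r_free_hat: float
    r_bound_hat: float
    intensity_ratio: float
    rss: float
    converged: bool
    n_points: int
    assay_kind: str
    flags: list[str] = field(default_factory=list)
    standard_errors: dict[str, float] | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def predict_anisotropy(fraction_bound, r_free, r_bound, intensity_ratio=1.0):
    """Observed anisotropy of a probe population with the given bound fraction.

    r = (Q FB r_b + (1-FB) r_f) / (Q FB + (1-FB)); with Q=1 this is the
    linear mix r_f + (r_b - r_f) FB.  Q > 1 means the bound state is brighter
    and weighs more in the intensity-weighted average.
    """
    fb = np.asarray(fraction_bound, dtype=float)
    if np.any(fb < -1e-12) or np.any(fb > 1 + 1e-12):
        raise ValueError("fraction_bound must lie in [0, 1]")
    if not intensity_ratio > 0:
        raise ValueError("intensity_ratio must be > 0")
    fb = np.clip(fb, 0.0, 1.0)
    q = intensity_ratio
    r = (q * fb * r_bound + (1.0 - fb) * r_free) / (q * fb + (1.0 - fb))
    return r if r.ndim else float(r)


def _model(curve: TitrationCurve, titrant: np.ndarray, log10_kd: float,
           r_free: float, r_bound: float, q: float) -> np.ndarray:
    kd = 10.0**log10_kd
    if curve.assay_kind == "direct":
        fb = fraction_bound_direct(titrant, curve.probe_total, kd)
    else:
        r = free_receptor_competitive(
            curve.receptor_total, curve.probe_total, titrant, curve.kd_probe, kd
        )
        fb = r / (curve.kd_probe + r)
    return predict_anisotropy(fb, r_free, r_bound, q)


def _initial_guesses(curve: TitrationCurve, titrant, signal) -> list[np.ndarray]:
    pos = titrant[titrant > 0]
    lo, hi = pos.min(), pos.max()
    kd_inits = np.geomspace(lo, hi, 3)
    df = pd.DataFrame({"t": titrant, "a": signal}).groupby("t")["a"].mean()
    if curve.assay_kind == "direct":
        r_f0, r_b0 = df.iloc[0], df.iloc[-1]
        # extrapolate the top plateau if saturation was incomplete
        r_b0 = r_f0 + (r_b0 - r_f0) * 1.05
    else:
        # signal falls with competitor; top plateau sits at the It->0 bound fraction
        plateau, floor = df.iloc[0], df.iloc[-1]
        fb0 = fraction_bound_direct(curve.receptor_total, curve.probe_total, curve.kd_probe)
        r_f0 = floor
        r_b0 = r_f0 + (plateau - r_f0) / max(fb0, 1e-6)
    if r_b0 <= r_f0:
        r_b0 = r_f0 + max(abs(r_f0), 0.01)
    return [np.array([np.log10(k), r_f0, r_b0]) for k in kd_inits]


def fit_curve(curve: TitrationCurve, intensity_ratio: float = 1.0) -> BindingFitResult:
    """Fit a titration curve by multi-start nonlinear least squares.

    Three starts at log-spaced Kd values spanning the titrant range; the
    lowest-rss solution wins, ties going to the smaller Kd.  A fit is flagged
    not converged when the optimizer fails, the signal is constant, or the
    fitted endpoints are inverted (r_bound <= r_free).  Competition curves
    whose fitted signal never drops below 90% of the upper plateau get a
    ``lower_bound_only`` flag: the data only bound the Kd from below.
    """
    titrant, signal, _ = curve.arrays()
    flags: list[str] = []
    if np.ptp(signal) == 0:
        return BindingFitResult(
            kd_hat=np.nan, r_free_hat=float(signal[0]), r_bound_hat=float(signal[0]),
            intensity_ratio=intensity_ratio, rss=0.0, converged=False,
            n_points=len(signal), assay_kind=curve.assay_kind,
            flags=["constant_signal"],
        )

    def resid(params):
        return _model(curve, titrant, *params, intensity_ratio) - signal

    best = None
    for x0 in _initial_guesses(curve, titrant, signal):
        try:
            sol = least_squares(resid, x0, method="lm", ftol=1e-14, xtol=1e-14, gtol=1e-14)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None:
            best = (rss, sol)
        else:
            brss = best[0]
            tol = _RSS_TOL * max(brss, 1.0)
            if rss < brss - tol or (abs(rss - brss) <= tol and sol.x[0] < best[1].x[0]):
                best = (rss, sol)
    if best is None:
        return BindingFitResult(
            kd_hat=np.nan, r_free_hat=np.nan, r_bound_hat=np.nan,
            intensity_ratio=intensity_ratio, rss=np.inf, converged=False,
            n_points=len(signal), assay_kind=curve.assay_kind, flags=["optimizer_failed"],
        )
    rss, sol = best
    log10_kd, r_f, r_b = sol.x
    converged = bool(sol.success and r_b > r_f)
    if r_b <= r_f:
        flags.append("inverted_endpoints")
    if curve.assay_kind == "competition" and converged:
        pred_top = _model(curve, np.array([titrant.min()]), *sol.x, intensity_ratio)[0]
        pred_bot = _model(curve, np.array([titrant.max()]), *sol.x, intensity_ratio)[0]
        if pred_bot > _PLATEAU_DEPRESSION * pred_top:
            flags.append("lower_bound_only")
    return BindingFitResult(
        kd_hat=float(10.0**log10_kd), r_free_hat=float(r_f), r_bound_hat=float(r_b),
        intensity_ratio=intensity_ratio, rss=rss, converged=converged,
        n_points=len(signal), assay_kind=curve.assay_kind, flags=flags,
    )


def fit_direct(curve: TitrationCurve, intensity_ratio: float = 1.0) -> BindingFitResult:
    """Estimate the probe Kd from a direct (receptor-titration) curve."""
    if curve.assay_kind != "direct":
        raise ValueError("fit_direct requires a direct-assay curve")
    return fit_curve(curve, intensity_ratio)


def fit_competition(curve: TitrationCurve, intensity_ratio: float = 1.0) -> BindingFitResult:
    """Estimate the competitor Kd from a competition curve (probe Kd fixed)."""
    if curve.assay_kind != "competition":
        raise ValueError("fit_competition requires a competition-assay curve")
    return fit_curve(curve, intensity_ratio)


def estimate_uncertainty(
    curve: TitrationCurve,
    result: BindingFitResult,
    n_boot: int = 200,
    seed: int = 0,
) -> dict[str, float]:
    """Residual-bootstrap standard errors for (log10 Kd, Kd, r_free, r_bound).

    Residuals of the fitted curve are resampled with replacement onto the
    fitted values and each pseudo-dataset is refitted from the original
    solution.  Deterministic given ``seed``; results are stored back into
    ``result.standard_errors``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if not result.converged:
        raise ValueError("uncertainty requires a converged fit")
    titrant, signal, _ = curve.arrays()
    x_hat = np.array([np.log10(result.kd_hat), result.r_free_hat, result.r_bound_hat])
    fitted = _model(curve, titrant, *x_hat, result.intensity_ratio)
    residuals = signal - fitted
    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, 3))
    for b in range(n_boot):
        y_star = fitted + rng.choice(residuals, size=residuals.size, replace=True)

        def resid(params):
            return _model(curve, titrant, *params, result.intensity_ratio) - y_star

        sol = least_squares(resid, x_hat, method="lm", ftol=1e-12, xtol=1e-12)
        draws[b] = sol.x
    ses = draws.std(axis=0, ddof=1)
    kd_draws = 10.0 ** draws[:, 0]
    out = {
        "log10_kd": float(ses[0]),
        "kd": float(kd_draws.std(ddof=1)),
        "r_free": float(ses[1]),
        "r_bound": float(ses[2]),
    }
    result.standard_errors = out
    return out


# ---------------------------------------------------------------------------
# delimited-text I/O: '# key: value' header lines, then titrant_nM /
# anisotropy / replicate columns
# ---------------------------------------------------------------------------

_META_FLOAT = {"probe_total_nM", "receptor_total_nM", "kd_probe_nM"}


def write_curve(curve: TitrationCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# assay_kind: {curve.assay_kind}\n")
        fh.write(f"# probe_total_nM: {curve.probe_total!r}\n")
        if curve.receptor_total is not None:
            fh.write(f"# receptor_total_nM: {curve.receptor_total!r}\n")
        if curve.kd_probe is not None:
            fh.write(f"# kd_probe_nM: {curve.kd_probe!r}\n")
        for k, v in curve.meta.items():
            fh.write(f"# {k}: {v}\n")
        fh.write("titrant_nM\tanisotropy\treplicate\n")
        for p in curve.points:
            fh.write(f"{p.titrant!r}\t{p.anisotropy!r}\t{p.replicate_id}\n")


def read_curve(path) -> TitrationCurve:
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    import io

    df = pd.read_csv(io.StringIO("".join(lines[body_start:])), sep="\t",
                     float_precision="round_trip")
    if "assay_kind" not in meta:
        raise ValueError(f"{path}: missing required 'assay_kind' header")
    if "probe_total_nM" not in meta:
        raise ValueError(f"{path}: missing required 'probe_total_nM' header")
    points = [
        TitrationPoint(float(t), float(a), int(r))
        for t, a, r in zip(df["titrant_nM"], df["anisotropy"], df["replicate"])
    ]
    extra = {k: v for k, v in meta.items()
             if k not in _META_FLOAT and k != "assay_kind"}
    return TitrationCurve(
        assay_kind=meta["assay_kind"],
        probe_total=float(meta["probe_total_nM"]),
        receptor_total=float(meta["receptor_total_nM"]) if "receptor_total_nM" in meta else None,
        kd_probe=float(meta["kd_probe_nM"]) if "kd_probe_nM" in meta else None,
        points=points,
        meta=extra,
    )


def fit_results_to_frame(results: dict[str, BindingFitResult]) -> pd.DataFrame:
    rows = []
    for name, res in results.items():
        d = res.to_dict()
        ses = d.pop("standard_errors") or {}
        d.pop("flags")
        d["flags"] = ";".join(res.flags)
        d["se_kd"] = ses.get("kd", np.nan)
        d["se_log10_kd"] = ses.get("log10_kd", np.nan)
        rows.append({"oligo": name, **d})
    return pd.DataFrame(rows)


def write_fit_results(results: dict[str, BindingFitResult], tsv_path=None, json_path=None) -> None:
    frame = fit_results_to_frame(results)
    if tsv_path is not None:
        frame.to_csv(tsv_path, sep="\t", index=False, float_format="%.15g")
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump({k: v.to_dict() for k, v in results.items()}, fh, indent=1)
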