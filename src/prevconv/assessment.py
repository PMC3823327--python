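"""Stream-specific deviances and DIC for comparing kernel/process variants.

Fit is reported separately for the three observation streams (prevalence
counts y, hospitalisation counts M, air quality x) because their scales are
not commensurable — there is deliberately no composite single-number fit.

Poisson streams use the saturated deviance, 2 sum[y log(y/mu) - (y - mu)],
which is zero at a perfect fit; the Gaussian stream uses -2 x log likelihood.
DIC = D-bar + pD with pD = D-bar - D(theta-bar).  The plug-in deviance is
evaluated at the posterior mean of the fitted means (mean of E*rho draws,
mean of mu_x draws, mean var_x), not at parameter-wise posterior means,
avoiding the log-scale Jensen asymmetry of the latter.  pD can come out
negative and is reported as computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "poisson_deviance",
    "gaussian_deviance",
    "dic",
    "DicReport",
    "dic_report",
]


def poisson_deviance(count, mean) -> float:
    """Saturated Poisson deviance with the 0 log 0 = 0 convention."""
    count = np.asarray(count, dtype=float)
    mean = np.asarray(mean, dtype=float)
    if np.any(mean <= 0) or not np.all(np.isfinite(mean)):
        raise ValueError("Poisson means must be positive and finite")
    term = np.zeros_like(mean)
    pos = count > 0
    term[pos] = count[pos] * np.log(count[pos] / mean[pos])
    return float(2.0 * np.sum(term - (count - mean)))


def gaussian_deviance(x, mu, var_x: float) -> float:
    """-2 x Gaussian log likelihood of the air-quality stream."""
    from .model import loglik_airquality

    return -2.0 * loglik_airquality(x, mu, var_x)


def dic(deviance_draws, plug_in_deviance: float) -> tuple[float, float, float]:
    """(DIC, pD, D-bar) from per-draw deviances and a plug-in deviance."""
    deviance_draws = np.asarray(deviance_draws, dtype=float).reshape(-1)
    if deviance_draws.size == 0:
        raise ValueError("no deviance draws")
    d_bar = float(deviance_draws.mean())
    p_d = d_bar - float(plug_in_deviance)
    return d_bar + p_d, p_d, d_bar


@dataclass(frozen=True)
class DicReport:
    """Per-stream DIC decomposition for one fitted model variant."""

    streams: dict[str, dict[str, float]]  # stream -> {dic, p_d, d_bar, d_hat}

    def to_frame(self, label: str | None = None) -> pd.DataFrame:
        rows = []
        for stream, vals in self.streams.items():
            row = {"stream": stream, **vals}
            if label is not None:
                row = {"model": label, **row}
            rows.append(row)
        return pd.DataFrame(rows)

    def __getitem__(self, stream: str) -> dict[str, float]:
        return self.streams[stream]


def dic_report(draws, source, target) -> DicReport:
    """Compute the three per-stream DICs from posterior draws.

    ``draws`` is a PosteriorDraws; plug-in fitted means are posterior means
    of E*rho (y stream), G*nu (M stream) and (mu_x, var_x) for the x stream.
    """
    if draws.n_chains * draws.n_draws < 100:
        raise ValueError("DIC needs at least 100 retained draws")
    y = source.count
    E = source.offset_prevalence
    M = target.count
    G = target.offset_morbidity
    x = target.covariate

    mu_y_hat = E * draws.stacked("rho_source").mean(axis=0)
    mu_m_hat = G * draws.stacked("nu").mean(axis=0)
    mu_x_hat = draws.stacked("mu_x").mean(axis=0)
    var_x_hat = float(draws.stacked("var_x").mean())

    streams = {}
    for name, dev_draws, d_hat in (
        ("y", draws.deviance_y, poisson_deviance(y, mu_y_hat)),
        ("M", draws.deviance_m, poisson_deviance(M, mu_m_hat)),
        ("x", draws.deviance_x, gaussian_deviance(x, mu_x_hat, var_x_hat)),
    ):
        dic_val, p_d, d_bar = dic(dev_draws, d_hat)
        streams[name] = {"dic": dic_val, "p_d": p_d, "d_bar": d_bar, "d_hat": d_hat}
    return DicReport(streams=streams)
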