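"""Synthetic city-by-year panels with a known production frontier.

The real yearbook panel behind the benchmarking study is not
machine-retrievable, so every pipeline stage is exercised on generated
panels whose ground truth is known:

* inputs x are log-normal;
* a Cobb-Douglas frontier with per-period technology drift defines maximal
  output, and each unit produces a fraction theta_it of it (its true
  efficiency), theta linked to covariates z through known coefficients
  beta_true plus a unit random effect — exactly the structure the
  second-stage Tobit regression assumes;
* one undesirable output rises with production, with multiplicative noise.

The module also packages the transcribed matrix of published comprehensive
efficiency scores for the 41 Yangtze-River-Delta cities, 2015-2020, used by
the reporting tests (:func:`table4_fixture`).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .panel import PanelDataset

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_panel",
           "table4_fixture", "FIXTURE_SHA256"]

FIXTURE_SHA256 = "7ba99f261c70fd25f6cf1beda06e054f3f4c27318480d56d93669a1ce14f160c"

#: default covariate coefficients on the latent-efficiency scale; a mix of
#: strong positive/negative effects and exact nulls for calibration tests
_DEFAULT_BETA = (0.5, 0.35, -0.4, 0.3, 0.0, -0.35, 0.0, 0.3)


@dataclass(frozen=True)
class SyntheticConfig:
    """Data-generating configuration.

    Default dimensions mirror the benchmark study: 41 units, 6 periods,
    3 inputs, 2 desirable outputs, 1 undesirable output, 8 covariates.

    rts_degree
        sum of the Cobb-Douglas input exponents (1.0 = constant returns).
    tech_drift
        multiplicative frontier growth per period (frontier multiplier in
        period t is tech_drift**t).
    sigma_u, sigma_e
        SDs of the unit random effect and idiosyncratic noise on the
        latent-efficiency scale.
    output_noise, bad_noise
        SDs of the multiplicative log-normal noise on outputs and on the
        undesirable output.
    anchor_frontier
        rescale each period's efficiencies by the period maximum so the
        best unit has true efficiency exactly 1 (and produces exactly
        frontier output, its output noise suppressed).
    """

    n_units: int = 41
    T: int = 6
    m: int = 3
    q: int = 2
    h: int = 1
    p: int = 8
    first_period: int = 2015
    rts_degree: float = 1.0
    tech_drift: float = 1.03
    beta_true: tuple = _DEFAULT_BETA
    sigma_u: float = 0.2
    sigma_e: float = 0.15
    output_noise: float = 0.05
    bad_noise: float = 0.05
    input_sd: float = 0.3
    anchor_frontier: bool = True
    n_groups: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_units < 2 or self.T < 1:
            raise ValueError("need n_units >= 2 and T >= 1")
        if self.m < 1 or self.q < 1 or self.h < 0 or self.p < 0:
            raise ValueError("invalid dimension counts")
        if len(self.beta_true) != self.p:
            raise ValueError("beta_true length must equal p")
        if self.rts_degree <= 0:
            raise ValueError("rts_degree must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated panel."""

    frontier_exponents: np.ndarray          # per-input, sums to rts_degree
    true_efficiency: pd.DataFrame           # unit x period matrix of theta
    tech_drift: np.ndarray                  # per-period frontier multiplier
    beta_true: np.ndarray
    sigma_u_true: float
    sigma_e_true: float
    seed: int


def _exponents(m: int, degree: float) -> np.ndarray:
    # fixed decreasing shares, normalized to the requested degree
    raw = np.arange(m, 0, -1, dtype=float) + m
    return raw / raw.sum() * degree


def generate_panel(config: SyntheticConfig = SyntheticConfig()
                   ) -> tuple[PanelDataset, SyntheticTruth]:
    """Generate one panel and its ground truth.

    Deterministic: the same config (including seed) regenerates a
    bit-identical dataset.  All draws come from a single
    ``numpy.random.default_rng(seed)`` stream; no global state.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, T, m, q, h, p = cfg.n_units, cfg.T, cfg.m, cfg.q, cfg.h, cfg.p
    units = [f"city{str(i + 1).zfill(2)}" for i in range(n)]
    periods = [cfg.first_period + t for t in range(T)]
    alpha = _exponents(m, cfg.rts_degree)
    drift = cfg.tech_drift ** np.arange(T)

    # inputs: log-normal around unit-specific size levels
    size = rng.normal(0.0, 0.4, size=n)                     # persistent city size
    x = np.exp(size[:, None, None]
               + rng.normal(0.0, cfg.input_sd, size=(n, T, m)))

    # covariates and latent efficiency
    z = rng.normal(0.0, 1.0, size=(n, T, p)) if p else np.zeros((n, T, 0))
    u = rng.normal(0.0, cfg.sigma_u, size=n)
    eps = rng.normal(0.0, cfg.sigma_e, size=(n, T))
    beta = np.asarray(cfg.beta_true, float)
    eta = (z @ beta if p else np.zeros((n, T))) + u[:, None] + eps
    theta = 1.0 / (1.0 + np.exp(-eta))                      # in (0, 1)
    anchor_idx = np.full(T, -1)
    if cfg.anchor_frontier:
        # per period, rescale by the maximum so the best unit sits at 1
        anchor_idx = theta.argmax(axis=0)
        theta = theta / theta.max(axis=0, keepdims=True)

    # frontier output and realized outputs
    frontier = drift[None, :] * np.prod(x ** alpha[None, None, :], axis=2)
    out_scale = 1.0 + 0.5 * np.arange(q)                    # per-output level
    noise_y = np.exp(rng.normal(0.0, cfg.output_noise, size=(n, T, q)))
    if cfg.anchor_frontier:
        for t in range(T):
            noise_y[anchor_idx[t], t, :] = 1.0              # anchor exactly on frontier
    y = (frontier * theta)[:, :, None] * out_scale[None, None, :] * noise_y

    # undesirable output: increases with production, multiplicative noise
    noise_b = np.exp(rng.normal(0.0, cfg.bad_noise, size=(n, T, h))) if h else None
    b = 0.3 * y[:, :, :1].repeat(h, axis=2) * noise_b if h else np.zeros((n, T, 0))

    rows = []
    for i, unit in enumerate(units):
        for t, period in enumerate(periods):
            row = {"unit": unit, "period": period,
                   "group": f"group{(i % cfg.n_groups) + 1}"}
            row.update({f"x{j+1}": x[i, t, j] for j in range(m)})
            row.update({f"y{r+1}": y[i, t, r] for r in range(q)})
            row.update({f"b{k+1}": b[i, t, k] for k in range(h)})
            row.update({f"z{s+1}": z[i, t, s] for s in range(p)})
            rows.append(row)
    frame = pd.DataFrame(rows)
    data = PanelDataset(
        frame=frame,
        inputs=tuple(f"x{j+1}" for j in range(m)),
        outputs=tuple(f"y{r+1}" for r in range(q)),
        bads=tuple(f"b{k+1}" for k in range(h)),
        covariates=tuple(f"z{s+1}" for s in range(p)),
        has_group=True,
    )
    truth = SyntheticTruth(
        frontier_exponents=alpha,
        true_efficiency=pd.DataFrame(theta, index=units, columns=periods),
        tech_drift=drift,
        beta_true=beta,
        sigma_u_true=cfg.sigma_u,
        sigma_e_true=cfg.sigma_e,
        seed=cfg.seed,
    )
    return data, truth


def table4_fixture() -> pd.DataFrame:
    """Published comprehensive efficiency scores, 41 cities x 6 years.

    Columns: ``city``, ``province``, ``y2015`` ... ``y2020``, and the
    printed ``average`` and ``rank`` columns.  The final ``All`` row holds
    the printed per-year region averages (rank empty).  The packaged CSV is
    checksummed; two same-named city pairs are disambiguated with province
    suffixes.
    """
    ref = resources.files("healtheff.data") / "city_efficiency_2015_2020.csv"
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != FIXTURE_SHA256:
        raise RuntimeError(
            f"packaged efficiency fixture corrupted (sha256 {digest})")
    import io
    df = pd.read_csv(io.BytesIO(raw))
    assert df.shape == (42, 10)
    return df
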