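"""Synthetic retention studies with a shared latent-lipophilicity factor.

The generator emulates the statistical structure the analysis pipeline
assumes: each compound i carries one latent lipophilicity L_i, every
system s maps it affinely to a true extrapolated intercept

    A_is = offset_s + gain_s * L_i,

the true slope is coupled to the intercept, B_is = -(c0 + c1 * A_is) < 0
(more lipophilic solutes respond more steeply to modifier), and the
observed retention at each grid point phi is y = A_is + B_is * phi plus
Gaussian measurement noise.  Planar systems emit retardation factors
R_F = 1 / (1 + 10^y), censored to the measurable window; column systems
emit retention times t_R = t0 * (1 + 10^y) at fixed dead time.  Computed
log P / log D descriptors are affine-plus-noise images of the same latent,
so a dominant first principal component across systems is built in.

Default per-system offsets and gains reproduce the location and spread of
the 13-system study design; the latent factor is standard normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .systems import STUDY_SYSTEMS, ChromSystem, systems_frame

__all__ = ["GeneratorConfig", "SyntheticStudy", "generate"]

#: per-system (offset, gain) of the latent -> intercept map, matching the
#: study design's per-system mean and standard deviation of the
#: extrapolated lipophilicity parameter.
DEFAULT_SYSTEM_PARAMS: dict[str, tuple[float, float]] = {
    "T-C18-MET": (4.3424, 1.0561),
    "T-C18-ACN": (2.4181, 0.7871),
    "T-C18-ACE": (3.7951, 1.0156),
    "T-C18-DIO": (4.0096, 1.2277),
    "T-C8-MET": (4.1334, 1.0851),
    "T-C8-ACN": (2.8262, 0.8329),
    "T-C8-ACE": (3.5870, 1.1021),
    "T-C8-DIO": (3.8056, 1.2498),
    "C-C18-MET": (4.0104, 1.0563),
    "C-C8-MET": (5.0122, 0.9748),
    "C-C8-ACN": (2.3201, 0.5503),
    "C-IAM": (2.5658, 0.7299),
    "C-CHOL": (4.4297, 1.0041),
}

#: computed-descriptor emulation: name -> (offset, gain, noise sd) of the
#: affine map from the latent factor.
DEFAULT_INSILICO_PARAMS: dict[str, tuple[float, float, float]] = {
    "ChA log P": (3.40, 1.20, 0.12),
    "ALOGP": (3.70, 1.00, 0.12),
    "Clog P": (3.20, 1.40, 0.15),
    "Mlog P": (2.50, 0.85, 0.10),
    "S+log D": (3.50, 0.95, 0.12),
    "log D_7.4": (3.50, 1.50, 0.15),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic study.

    ``system_params`` maps system id -> (offset, gain); ``slope_coupling``
    holds (c0, c1) of B = -(c0 + c1 * A).  ``noise_sd`` is the Gaussian
    measurement noise on R_M / log k in log units; ``rf_window`` the
    measurable retardation-factor interval outside which planar points are
    censored.  The seed fully determines the output.
    """

    n_compounds: int = 18
    systems: tuple[ChromSystem, ...] = STUDY_SYSTEMS
    latent_sd: float = 1.0
    system_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SYSTEM_PARAMS))
    slope_coupling: tuple[float, float] = (0.5, 0.9)
    noise_sd: float = 0.05
    insilico_params: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_INSILICO_PARAMS))
    rf_window: tuple[float, float] = (0.03, 0.97)
    t0: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.latent_sd < 0:
            raise ValueError("latent_sd must be non-negative")
        if not (0.0 <= self.rf_window[0] < self.rf_window[1] <= 1.0):
            raise ValueError("rf_window must be an interval within [0, 1]")
        if self.seed < 0 or self.seed >= 2**31:
            raise ValueError("seed must be in [0, 2^31)")
        unknown = [s.id for s in self.systems if s.id not in self.system_params]
        if unknown:
            raise ValueError(f"systems without (offset, gain) parameters: {unknown}")


@dataclass(frozen=True)
class SyntheticStudy:
    """Generated study: observations, ground truth, and censoring log."""

    config: GeneratorConfig
    retention: pd.DataFrame     # compound_id, system_id, phi, rf, tr, t0
    systems: pd.DataFrame       # the systems.csv dialect
    insilico: pd.DataFrame      # compound_id-indexed computed descriptors
    truth: pd.DataFrame         # compound_id, system_id, latent, intercept, slope
    censored: pd.DataFrame      # planar points dropped by the rf window
    exclusions: pd.DataFrame    # (compound, system) with < 3 usable points

    def write(self, outdir) -> dict[str, Path]:
        """Write retention/systems/insilico/truth/censored CSVs; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df, use_index in (
                ("retention", self.retention, False),
                ("systems", self.systems, False),
                ("insilico", self.insilico, True),
                ("truth", self.truth, False),
                ("censored", self.censored, False)):
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=use_index)
            paths[name] = p
        return paths


def _true_slope(cfg: GeneratorConfig, intercept: np.ndarray) -> np.ndarray:
    c0, c1 = cfg.slope_coupling
    return -(c0 + c1 * intercept)


def generate(config: GeneratorConfig | None = None, **overrides) -> SyntheticStudy:
    """Draw one synthetic study from the latent-factor model.

    One seed sequence drives the whole call; per-(compound, system) noise
    uses deterministically derived sub-streams, so regenerating with the
    same configuration is reproducible bit for bit.
    """
    cfg = config or GeneratorConfig()
    if overrides:
        cfg = replace(cfg, **overrides)
    compounds = [str(i + 1) for i in range(cfg.n_compounds)]
    latent = np.random.default_rng([cfg.seed, 0]).normal(
        0.0, cfg.latent_sd, size=cfg.n_compounds)

    ret_rows, truth_rows, cens_rows, excl_rows = [], [], [], []
    for s_idx, system in enumerate(cfg.systems):
        offset, gain = cfg.system_params[system.id]
        a_true = offset + gain * latent
        b_true = _true_slope(cfg, a_true)
        grid = system.phi_grid()
        for c_idx, cid in enumerate(compounds):
            rng = np.random.default_rng([cfg.seed, 1, c_idx, s_idx])
            y = a_true[c_idx] + b_true[c_idx] * grid \
                + rng.normal(0.0, cfg.noise_sd, size=grid.size)
            truth_rows.append({"compound_id": cid, "system_id": system.id,
                               "latent": latent[c_idx],
                               "intercept": a_true[c_idx],
                               "slope": b_true[c_idx]})
            n_usable = 0
            for phi, yi in zip(grid, y):
                if system.technique == "HPTLC":
                    rf = 1.0 / (1.0 + 10.0**yi)
                    if not (cfg.rf_window[0] <= rf <= cfg.rf_window[1]):
                        cens_rows.append({"compound_id": cid,
                                          "system_id": system.id,
                                          "phi": phi, "rf": rf})
                        continue
                    ret_rows.append({"compound_id": cid, "system_id": system.id,
                                     "phi": phi, "rf": rf,
                                     "tr": np.nan, "t0": np.nan})
                else:
                    tr = cfg.t0 * (1.0 + 10.0**yi)
                    ret_rows.append({"compound_id": cid, "system_id": system.id,
                                     "phi": phi, "rf": np.nan,
                                     "tr": tr, "t0": cfg.t0})
                n_usable += 1
            if n_usable < 3:
                excl_rows.append({"compound_id": cid, "system_id": system.id,
                                  "n_usable": n_usable})

    if excl_rows:
        warnings.warn(
            f"{len(excl_rows)} (compound, system) series have fewer than 3 "
            "usable points and cannot be fitted", stacklevel=2)

    ins_rng = np.random.default_rng([cfg.seed, 2])
    ins = {}
    for name, (off, gn, sd) in cfg.insilico_params.items():
        ins[name] = off + gn * latent + ins_rng.normal(0.0, sd, size=cfg.n_compounds)
    insilico = pd.DataFrame(ins, index=pd.Index(compounds, name="compound_id"))

    cens_cols = ["compound_id", "system_id", "phi", "rf"]
    excl_cols = ["compound_id", "system_id", "n_usable"]
    return SyntheticStudy(
        config=cfg,
        retention=pd.DataFrame(ret_rows,
                               columns=["compound_id", "system_id", "phi",
                                        "rf", "tr", "t0"]),
        systems=systems_frame(cfg.systems),
        insilico=insilico,
        truth=pd.DataFrame(truth_rows),
        censored=pd.DataFrame(cens_rows, columns=cens_cols),
        exclusions=pd.DataFrame(excl_rows, columns=excl_cols),
    )
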