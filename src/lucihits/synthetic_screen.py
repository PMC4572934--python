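"""Seeded generator of synthetic reporter screens and dose-response series.

The generator emulates a Prestwick-style screen: four 384-well library
plates, each assayed in triplicate, with on-plate DMSO / GW4064 / TNFa /
GW4064+TNFa controls and 300 library compounds per plate dosed in the
presence of TNFa. It provides the ground truth (which compounds truly
inhibit, which are cytotoxic) that downstream tests score against.

Noise model
-----------
Both reporters carry multiplicative mean-one lognormal measurement noise,
independent between firefly and renilla. A single multiplicative plate
effect per (plate, replicate) scales both reporters, mimicking
transfection-batch variation; it cancels in the firefly/renilla ratio, so
per-plate normalization absorbs it by construction. Cytotoxic compounds
lose both reporters proportionally (cells dying), which leaves the ratio
unbiased in expectation but depresses renilla -- the failure mode the
viability filter targets.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .plate_model import PlateLayout, ScreenDataset

__all__ = [
    "SyntheticScreenConfig",
    "build_default_layout",
    "generate_screen",
    "generate_dose_response",
    "four_pl",
]


@dataclass(frozen=True)
class SyntheticScreenConfig:
    """Study conditions for a synthetic screen.

    Parameters
    ----------
    n_library_plates, n_replicates, plate_format
        Screen scale; defaults mirror a four-plate 384-well library
        assayed in triplicate.
    compounds_per_plate
        Library compounds per plate (300 x 4 = the 1,200-compound library).
    tnfa_baseline_rlu, dmso_baseline_rlu
        Mean firefly/renilla ratio of induced (TNFa) and uninduced (DMSO)
        wells, arbitrary units; the ~10-fold span is typical of an NF-kB
        reporter.
    gw_inhibition_frac
        Fractional reduction of the TNFa-induced component by the
        reference agonist control.
    frac_true_inhibitors, inhibition_lo, inhibition_hi
        Fraction of library compounds with a real effect and the uniform
        range their fractional inhibition is drawn from.
    frac_cytotoxic, cytotoxic_renilla_frac
        Fraction of compounds that kill cells and the residual renilla
        fraction those wells retain.
    measurement_cv
        Coefficient of variation of the lognormal measurement noise,
        applied independently to each reporter.
    plate_effect_sd
        SD (log scale) of the per-(plate, replicate) multiplicative factor.
    renilla_mean
        Mean renilla counts of healthy wells.
    """

    n_library_plates: int = 4
    n_replicates: int = 3
    plate_format: int = 384
    compounds_per_plate: int = 300
    tnfa_baseline_rlu: float = 2.0
    dmso_baseline_rlu: float = 0.2
    gw_inhibition_frac: float = 0.5
    frac_true_inhibitors: float = 0.05
    inhibition_lo: float = 0.7
    inhibition_hi: float = 0.9
    frac_cytotoxic: float = 0.02
    cytotoxic_renilla_frac: float = 0.3
    measurement_cv: float = 0.1
    plate_effect_sd: float = 0.15
    renilla_mean: float = 5000.0
    library_concentration_M: float = 1e-5
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_true_inhibitors", "frac_cytotoxic",
                     "gw_inhibition_frac", "cytotoxic_renilla_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.measurement_cv < 0 or self.plate_effect_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0.0 <= self.inhibition_lo <= self.inhibition_hi <= 1.0:
            raise ValueError("inhibition range must satisfy 0 <= lo <= hi <= 1")

    def with_(self, **kw) -> "SyntheticScreenConfig":
        return replace(self, **kw)


def build_default_layout(plate_id: str, compound_ids: list[str],
                         plate_format: int = 384) -> PlateLayout:
    """Standard 384-well screening layout with edge-column controls.

    Columns 1 and 24 plus half of column 23 hold TNFa wells (40 in all):
    TNFa is both the normalization anchor and the sole source of the
    empirical null, whose smallest attainable p-value is 1/(n+1), so the
    pool must resolve probabilities below the significance level. Column 2
    holds DMSO (rows A-H) and GW4064 (rows I-P); column 23 rows A-H hold
    GW4064+TNFa. Library compounds fill columns 3-22 row-major.
    """
    if plate_format != 384:
        raise ValueError("default layout is defined for 384-well plates")
    rows = string.ascii_uppercase[:16]
    roles: dict[tuple[str, int], str] = {}
    compounds: dict[tuple[str, int], str] = {}
    for r in rows:
        roles[(r, 1)] = "TNFA"
        roles[(r, 24)] = "TNFA"
        roles[(r, 2)] = "DMSO" if r <= "H" else "GW4064"
        roles[(r, 23)] = "GW4064_TNFA" if r <= "H" else "TNFA"
    positions = [(r, c) for r in rows for c in range(3, 23)]
    if len(compound_ids) > len(positions):
        raise ValueError(
            f"{len(compound_ids)} compounds exceed {len(positions)} "
            "library positions"
        )
    for cid, pos in zip(compound_ids, positions):
        roles[pos] = "LIBRARY"
        compounds[pos] = cid
    return PlateLayout(plate_id, plate_format, roles, compounds)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def generate_screen(
    config: SyntheticScreenConfig,
) -> tuple[ScreenDataset, pd.DataFrame]:
    """Generate a seeded synthetic screen with ground truth.

    Returns
    -------
    dataset : ScreenDataset
        Validated screen; ``dataset.truth`` carries the ground truth.
    truth : pandas.DataFrame
        Columns ``compound_id, true_inhibition_fraction, is_cytotoxic``,
        one row per library compound.

    Notes
    -----
    Expected well model: each role/compound has a mean RLU (ratio);
    true inhibitors reduce the TNFa-induced component
    ``tnfa_baseline_rlu - dmso_baseline_rlu`` by their effect fraction.
    Measured renilla = renilla_mean x plate effect x cytotoxic factor x
    noise; measured firefly = mean RLU x measured renilla x noise. The
    ratio therefore carries a single mean-one lognormal factor and no
    plate effect. Identical seeds give identical datasets.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cfg = config

    n_cmpd = cfg.n_library_plates * cfg.compounds_per_plate
    compound_ids = [f"CMPD-{i + 1:04d}" for i in range(n_cmpd)]

    # ground truth: independent Bernoulli labels, effects ~ U[lo, hi]
    is_inhib = rng.random(n_cmpd) < cfg.frac_true_inhibitors
    effects = np.where(
        is_inhib, rng.uniform(cfg.inhibition_lo, cfg.inhibition_hi, n_cmpd), 0.0
    )
    is_cyto = rng.random(n_cmpd) < cfg.frac_cytotoxic
    truth = pd.DataFrame(
        {
            "compound_id": compound_ids,
            "true_inhibition_fraction": effects,
            "is_cytotoxic": is_cyto,
        }
    )
    effect_of = dict(zip(compound_ids, effects))
    cyto_of = dict(zip(compound_ids, is_cyto))

    induced = cfg.tnfa_baseline_rlu - cfg.dmso_baseline_rlu
    role_rlu = {
        "DMSO": cfg.dmso_baseline_rlu,
        "GW4064": cfg.dmso_baseline_rlu,
        "TNFA": cfg.tnfa_baseline_rlu,
        "GW4064_TNFA": cfg.dmso_baseline_rlu
        + induced * (1.0 - cfg.gw_inhibition_frac),
    }

    layouts: dict[str, PlateLayout] = {}
    frames = []
    for p in range(cfg.n_library_plates):
        plate_id = f"P{p + 1}"
        cids = compound_ids[
            p * cfg.compounds_per_plate : (p + 1) * cfg.compounds_per_plate
        ]
        layout = build_default_layout(plate_id, cids, cfg.plate_format)
        layouts[plate_id] = layout

        positions = sorted(layout.roles, key=lambda rc: (rc[0], rc[1]))
        roles = np.array([layout.roles[pos] for pos in positions])
        cmpds = np.array(
            [layout.compounds.get(pos, "") for pos in positions], dtype=object
        )
        mean_rlu = np.array(
            [
                cfg.dmso_baseline_rlu
                + induced * (1.0 - effect_of[layout.compounds[pos]])
                if layout.roles[pos] == "LIBRARY"
                else role_rlu[layout.roles[pos]]
                for pos in positions
            ]
        )
        cyto_factor = np.array(
            [
                cfg.cytotoxic_renilla_frac
                if layout.roles[pos] == "LIBRARY"
                and cyto_of[layout.compounds[pos]]
                else 1.0
                for pos in positions
            ]
        )
        n = len(positions)
        for rep in range(1, cfg.n_replicates + 1):
            plate_effect = (
                float(np.exp(rng.normal(0.0, cfg.plate_effect_sd)))
                if cfg.plate_effect_sd > 0
                else 1.0
            )
            renilla = (
                cfg.renilla_mean
                * plate_effect
                * cyto_factor
                * _lognormal_factor(rng, cfg.measurement_cv, n)
            )
            firefly = (
                mean_rlu * renilla * _lognormal_factor(rng, cfg.measurement_cv, n)
            )
            frames.append(
                pd.DataFrame(
                    {
                        "plate_id": plate_id,
                        "replicate": rep,
                        "row": [pos[0] for pos in positions],
                        "col": [pos[1] for pos in positions],
                        "role": roles,
                        "compound_id": cmpds.astype(str),
                        "concentration_M": np.where(
                            roles == "LIBRARY",
                            cfg.library_concentration_M,
                            np.nan,
                        ),
                        "firefly": firefly,
                        "renilla": renilla,
                    }
                )
            )

    wells = pd.concat(frames, ignore_index=True)
    wells = wells.sort_values(
        ["plate_id", "replicate", "row", "col"], kind="mergesort"
    ).reset_index(drop=True)
    dataset = ScreenDataset(wells, layouts, truth=truth)
    dataset.validate()
    return dataset, truth


def four_pl(conc, bottom: float, top: float, hill: float, ec50: float):
    """Four-parameter logistic response at the given concentrations.

    ``response = bottom + (top - bottom) / (1 + (ec50 / conc) ** hill)``;
    positive ``hill`` rises with concentration (agonist orientation).
    """
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / conc) ** hill)


def generate_dose_response(
    bottom: float,
    top: float,
    hill: float,
    ec50: float,
    concentrations,
    n_replicates: int = 3,
    noise_cv: float = 0.05,
    seed: int = 0,
    compound_id: str = "synthetic",
) -> pd.DataFrame:
    """Generate replicate responses around a 4PL mean curve.

    Responses carry multiplicative mean-one lognormal noise; ``noise_cv=0``
    is an exact evaluation of the mean model. Returns a long-format frame
    with columns ``compound_id, concentration_M, response, replicate``.
    """
    if ec50 <= 0:
        raise ValueError("ec50 must be > 0")
    conc = np.asarray(concentrations, dtype=float)
    if (conc <= 0).any():
        raise ValueError("concentrations must be > 0")
    rng = np.random.default_rng(seed)
    mean = four_pl(conc, bottom, top, hill, ec50)
    rows = []
    for rep in range(1, n_replicates + 1):
        resp = mean * _lognormal_factor(rng, noise_cv, conc.size)
        rows.append(
            pd.DataFrame(
                {
                    "compound_id": compound_id,
                    "concentration_M": conc,
                    "response": resp,
                    "replicate": rep,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
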