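"""Synthetic twin-cohort generator.

The analyses in this package were designed for a national twin registry
(MZ/DZ pairs nested in families, assessed at age 12 with exam outcomes at
16) whose individual-level data cannot be redistributed.  This module
generates seeded synthetic cohorts carrying the full structure those
analyses assume:

* paternal and maternal age at conception (correlated), SES, sex, zygosity;
* a latent "geek factor" per child built from additive-genetic (A),
  dominance (D) and non-shared environmental (E) components with the
  classical twin sharing structure (A: 1.0 MZ / 0.5 DZ; D: 1.0 / 0.25;
  E: uncorrelated), with A- and E-path moderation by standardized paternal
  age (GxE), a sex-specific direct paternal-age effect and covariate
  effects;
* three integer subscales (non-verbal IQ, CAST social, CAST RRB) loading
  on the latent factor with independent noise, discretized and clipped to
  their scale ranges;
* an attainment outcome driven by the computed GI composite (so that
  mediation paternal age -> GI -> attainment holds by construction),
  plus STEM exam outcomes and a rare autism flag.

Dedicated pair-level simulators (`simulate_twin_pairs`, `simulate_ae_pairs`,
`simulate_gxe_pairs`) generate twin traits directly on the latent scale for
variance-component experiments, where the composite's measurement noise
would otherwise dominate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from . import gi as gi_mod
from .errors import DomainError, SchemaError

__all__ = [
    "SimConfig",
    "TwinPair",
    "simulate_cohort",
    "simulate_cohort_frame",
    "paper_fit_preset",
    "load_preset",
    "cohort_to_frame",
    "frame_to_pairs",
    "write_cohort",
    "read_cohort",
    "simulate_twin_pairs",
    "simulate_ae_pairs",
    "simulate_gxe_pairs",
    "COHORT_COLUMNS",
]


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters of a synthetic twin cohort.

    Units: paternal/maternal age in years; ``beta_pa_*`` in GI units per
    year (the subscale map is calibrated to unit latent-to-composite
    slope, see docs); ``a0``/``d0``/``e0`` are unstandardized latent path
    coefficients; ``beta_a``/``beta_e`` moderate the A and E paths per
    standardized-paternal-age unit; ``b_gi_attain`` in attainment units
    per GI unit; ``direct_pa_attain`` in attainment units per year.
    """

    n_families: int = 4000
    prop_mz: float = 0.36
    paternal_age_dist: tuple = (34.0, 6.0, 18.0, 60.0)  # mean, sd, min, max (yr)
    maternal_paternal_age_corr: float = 0.7
    ses_effects: tuple = (0.0, 0.0)  # (on GI, on attainment), per SES s.d.
    ses_paternal_age_corr: float = 0.0
    beta_maternal_gi: float = 0.0  # GI units per maternal-age year
    beta_pa_male: float = 0.0
    beta_pa_female: float = 0.0
    a0: float = 2.01
    d0: float = 0.0
    e0: float = 1.73
    beta_a: float = 0.0
    beta_e: float = 0.0
    b_gi_attain: float = 0.0
    direct_pa_attain: float = 0.0
    subscale_loadings: tuple = (0.075, 0.025, 0.025)
    subscale_noise_sds: tuple = (1.5, 1.0, 1.0)
    subscale_baselines: tuple = (7.0, 3.0, 3.0)
    subscale_ranges: tuple = ((0, 60), (0, 13), (0, 13))
    attainment_noise_sd: float = 3.0
    autism_prevalence: float = 0.004
    stem_count_per_gi: float = 0.01
    stem_top2_logodds_per_gi: float = 0.0392  # log(1.04)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise DomainError("n_families must be >= 1")
        if not 0.0 <= self.prop_mz <= 1.0:
            raise DomainError("prop_mz must lie in [0, 1]")
        mean, sd, lo, hi = self.paternal_age_dist
        if sd <= 0 or not lo < hi:
            raise DomainError("paternal_age_dist must have sd > 0 and ordered bounds")
        if any(s <= 0 for s in self.subscale_noise_sds):
            raise DomainError("subscale noise sds must be > 0")
        if self.a0 <= 0 or self.e0 <= 0:
            raise DomainError("a0 and e0 must be > 0")
        if self.attainment_noise_sd <= 0:
            raise DomainError("attainment_noise_sd must be > 0")
        if all(l == 0 for l in self.subscale_loadings):
            raise DomainError("subscale loadings are all zero: latent factor unidentifiable")

    @property
    def expected_gi_baseline(self) -> float:
        """GI value of a child at the subscale baselines (centering constant)."""
        b1, b2, b3 = self.subscale_baselines
        return (b1 + 1.0) * ((b2 + 1.0) + (b3 + 1.0))


@dataclass
class TwinPair:
    """One family's two twins.  Tuple-valued fields are (twin 1, twin 2)."""

    family_id: int
    zygosity: str  # MZ | DZ
    sex: tuple  # ('M'|'F', 'M'|'F'); MZ pairs share sex
    paternal_age: float
    maternal_age: float
    ses: float
    nonverbal_iq: tuple
    cast_social: tuple
    cast_rrb: tuple
    attainment: tuple
    autism_flag: tuple
    stem_gcses: tuple = (0, 0)
    art_gcses: tuple = (0, 0)
    stem_top2: tuple = (False, False)

    def __post_init__(self) -> None:
        if self.zygosity not in ("MZ", "DZ"):
            raise SchemaError(f"zygosity must be MZ or DZ, got {self.zygosity!r}")
        if self.zygosity == "MZ" and self.sex[0] != self.sex[1]:
            raise SchemaError("MZ pairs must share sex")


#: required columns of the per-child cohort CSV, in order
COHORT_COLUMNS = [
    "family_id",
    "twin_order",
    "zygosity",
    "sex",
    "paternal_age",
    "maternal_age",
    "ses",
    "nonverbal_iq",
    "cast_social",
    "cast_rrb",
    "attainment",
    "autism_flag",
]
#: optional outcome columns emitted by the generator
EXTRA_COLUMNS = ["stem_gcses", "art_gcses", "stem_top2"]

_INT_COLUMNS = {"family_id", "twin_order", "nonverbal_iq", "cast_social", "cast_rrb", "stem_gcses", "art_gcses"}
_BOOL_COLUMNS = {"autism_flag", "stem_top2"}


def _paternal_age_draw(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    mean, sd, lo, hi = cfg.paternal_age_dist
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def simulate_cohort_frame(config: SimConfig) -> pd.DataFrame:
    """Simulate a cohort and return it as a per-child DataFrame.

    Deterministic for a fixed config (the seed is part of the config).
    Column layout matches the cohort CSV schema plus the generator's
    extra outcome columns.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    n = cfg.n_families
    pa_mean, pa_sd = cfg.paternal_age_dist[0], cfg.paternal_age_dist[1]

    is_mz = rng.random(n) < cfg.prop_mz
    pa = _paternal_age_draw(cfg, rng, n)
    pa_c = pa - pa_mean
    moderator = pa_c / pa_sd  # standardized paternal age, shared within family

    ma = 29.0 + cfg.maternal_paternal_age_corr * pa_c + rng.normal(0.0, 3.5, n)
    ma = np.clip(ma, 16.0, 45.0)

    r_sp = cfg.ses_paternal_age_corr
    ses = r_sp * (pa_c / pa_sd) + np.sqrt(max(1.0 - r_sp**2, 0.0)) * rng.normal(0.0, 1.0, n)

    # sexes: MZ share one draw, DZ twins independent
    sex1 = np.where(rng.random(n) < 0.5, "M", "F")
    sex2_dz = np.where(rng.random(n) < 0.5, "M", "F")
    sex2 = np.where(is_mz, sex1, sex2_dz)

    # latent twin components with classical sharing coefficients
    def shared_component(share: float) -> tuple[np.ndarray, np.ndarray]:
        fam = rng.normal(0.0, 1.0, n)
        ind1 = rng.normal(0.0, 1.0, n)
        ind2 = rng.normal(0.0, 1.0, n)
        w_f, w_i = np.sqrt(share), np.sqrt(1.0 - share)
        c1 = np.where(is_mz, fam, w_f * fam + w_i * ind1)
        c2 = np.where(is_mz, fam, w_f * fam + w_i * ind2)
        return c1, c2

    a1, a2 = shared_component(0.5)
    d1, d2 = shared_component(0.25)
    e1 = rng.normal(0.0, 1.0, n)
    e2 = rng.normal(0.0, 1.0, n)

    a_m = cfg.a0 + cfg.beta_a * moderator
    e_m = cfg.e0 + cfg.beta_e * moderator

    def latent(sex, a_comp, e_comp, d_comp):
        beta_pa = np.where(sex == "M", cfg.beta_pa_male, cfg.beta_pa_female)
        return (
            a_m * a_comp
            + cfg.d0 * d_comp
            + e_m * e_comp
            + beta_pa * pa_c
            + cfg.ses_effects[0] * ses
            + cfg.beta_maternal_gi * (ma - 29.0)
        )

    g1 = latent(sex1, a1, e1, d1)
    g2 = latent(sex2, a2, e2, d2)

    def subscales(g):
        out = []
        for k in range(3):
            lo, hi = cfg.subscale_ranges[k]
            cont = (
                cfg.subscale_baselines[k]
                + cfg.subscale_loadings[k] * g
                + rng.normal(0.0, cfg.subscale_noise_sds[k], n)
            )
            out.append(np.clip(np.rint(cont), lo, hi).astype(int))
        return out

    iq1, so1, rr1 = subscales(g1)
    iq2, so2, rr2 = subscales(g2)

    gi1 = gi_mod.compute_gi(iq1, so1, rr1, gi_mod.DEFAULT_VARIANT)
    gi2 = gi_mod.compute_gi(iq2, so2, rr2, gi_mod.DEFAULT_VARIANT)
    gi_ref = cfg.expected_gi_baseline

    def outcomes(gi_vals):
        attain = (
            cfg.b_gi_attain * (gi_vals - gi_ref)
            + cfg.direct_pa_attain * pa_c
            + cfg.ses_effects[1] * ses
            + rng.normal(0.0, cfg.attainment_noise_sd, n)
        )
        stem = np.clip(np.rint(4.0 + cfg.stem_count_per_gi * (gi_vals - gi_ref) + rng.normal(0.0, 1.2, n)), 0, 10).astype(int)
        art = np.clip(np.rint(3.0 + rng.normal(0.0, 1.2, n)), 0, 10).astype(int)
        logit_p = np.log(0.25 / 0.75) + cfg.stem_top2_logodds_per_gi * (gi_vals - gi_ref)
        top2 = rng.random(n) < 1.0 / (1.0 + np.exp(-logit_p))
        autism = rng.random(n) < cfg.autism_prevalence
        return attain, stem, art, top2, autism

    at1, st1, ar1, t21, au1 = outcomes(gi1)
    at2, st2, ar2, t22, au2 = outcomes(gi2)

    fam_ids = np.arange(1, n + 1)
    zyg = np.where(is_mz, "MZ", "DZ")

    rows = {
        "family_id": np.repeat(fam_ids, 2),
        "twin_order": np.tile([1, 2], n),
        "zygosity": np.repeat(zyg, 2),
        "sex": np.stack([sex1, sex2], axis=1).ravel(),
        "paternal_age": np.repeat(pa, 2),
        "maternal_age": np.repeat(ma, 2),
        "ses": np.repeat(ses, 2),
        "nonverbal_iq": np.stack([iq1, iq2], axis=1).ravel(),
        "cast_social": np.stack([so1, so2], axis=1).ravel(),
        "cast_rrb": np.stack([rr1, rr2], axis=1).ravel(),
        "attainment": np.stack([at1, at2], axis=1).ravel(),
        "autism_flag": np.stack([au1, au2], axis=1).ravel(),
        "stem_gcses": np.stack([st1, st2], axis=1).ravel(),
        "art_gcses": np.stack([ar1, ar2], axis=1).ravel(),
        "stem_top2": np.stack([t21, t22], axis=1).ravel(),
    }
    return pd.DataFrame(rows)


def simulate_cohort(config: SimConfig) -> list[TwinPair]:
    """Simulate a cohort as a list of :class:`TwinPair` (see frame variant)."""
    return frame_to_pairs(simulate_cohort_frame(config))


def load_preset(name: str = "paper_fit", path=None) -> SimConfig:
    """Load a named SimConfig preset from a YAML config file.

    The file maps preset names to SimConfig fields; the packaged file
    ships the ``paper_fit`` preset.  Unknown fields are rejected.
    """
    if path is None:
        text = resources.files("geekdex").joinpath("presets.yaml").read_text()
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    presets = yaml.safe_load(text)
    if name not in presets:
        raise KeyError(f"preset {name!r} not found; available: {sorted(presets)}")
    raw = dict(presets[name])
    valid = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise SchemaError(f"unknown SimConfig fields in preset {name!r}: {sorted(unknown)}")
    for key in ("paternal_age_dist", "ses_effects", "subscale_loadings", "subscale_noise_sds", "subscale_baselines"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if "subscale_ranges" in raw:
        raw["subscale_ranges"] = tuple(tuple(r) for r in raw["subscale_ranges"])
    return SimConfig(**raw)


def paper_fit_preset() -> SimConfig:
    """The shipped preset whose generating parameters are the fitted values
    reported for the real cohort: sex-specific paternal-age effects 0.28 (M)
    and 0.09 (F) GI units/yr, latent paths a0=2.01 / e0=1.73 with moderation
    beta_a=0.08 / beta_e=0.02 per moderator s.d., GI->attainment 0.17 and a
    zero direct paternal-age effect on attainment (full mediation)."""
    return load_preset("paper_fit")


# ---------------------------------------------------------------------------
# pair <-> frame <-> CSV plumbing


def cohort_to_frame(pairs) -> pd.DataFrame:
    """Convert TwinPair records to the per-child DataFrame layout."""
    cols = COHORT_COLUMNS + EXTRA_COLUMNS
    rows = []
    for p in pairs:
        for j in (0, 1):
            rows.append(
                (
                    p.family_id,
                    j + 1,
                    p.zygosity,
                    p.sex[j],
                    p.paternal_age,
                    p.maternal_age,
                    p.ses,
                    p.nonverbal_iq[j],
                    p.cast_social[j],
                    p.cast_rrb[j],
                    p.attainment[j],
                    p.autism_flag[j],
                    p.stem_gcses[j],
                    p.art_gcses[j],
                    p.stem_top2[j],
                )
            )
    df = pd.DataFrame(rows, columns=cols)
    if len(df) == 0:
        df = pd.DataFrame({c: pd.Series(dtype=("int64" if c in _INT_COLUMNS else "bool" if c in _BOOL_COLUMNS else "object")) for c in cols})
    return df


def frame_to_pairs(df: pd.DataFrame) -> list[TwinPair]:
    """Group a per-child frame into TwinPair records (twin_order 1 then 2)."""
    pairs = []
    for fid, grp in df.groupby("family_id", sort=True):
        grp = grp.sort_values("twin_order")
        if len(grp) != 2:
            raise SchemaError(f"family {fid} has {len(grp)} rows; expected 2 twins")
        r1, r2 = grp.iloc[0], grp.iloc[1]
        pairs.append(
            TwinPair(
                family_id=int(fid),
                zygosity=str(r1["zygosity"]),
                sex=(str(r1["sex"]), str(r2["sex"])),
                paternal_age=float(r1["paternal_age"]),
                maternal_age=float(r1["maternal_age"]),
                ses=float(r1["ses"]),
                nonverbal_iq=(int(r1["nonverbal_iq"]), int(r2["nonverbal_iq"])),
                cast_social=(int(r1["cast_social"]), int(r2["cast_social"])),
                cast_rrb=(int(r1["cast_rrb"]), int(r2["cast_rrb"])),
                attainment=(float(r1["attainment"]), float(r2["attainment"])),
                autism_flag=(bool(r1["autism_flag"]), bool(r2["autism_flag"])),
                stem_gcses=(int(r1.get("stem_gcses", 0)), int(r2.get("stem_gcses", 0))),
                art_gcses=(int(r1.get("art_gcses", 0)), int(r2.get("art_gcses", 0))),
                stem_top2=(bool(r1.get("stem_top2", False)), bool(r2.get("stem_top2", False))),
            )
        )
    return pairs


def write_cohort(pairs_or_frame, path) -> None:
    """Write a cohort to the documented CSV schema (UTF-8, header, '.' decimals)."""
    df = pairs_or_frame if isinstance(pairs_or_frame, pd.DataFrame) else cohort_to_frame(pairs_or_frame)
    df.to_csv(path, index=False)


def read_cohort(path) -> list[TwinPair]:
    """Read a cohort CSV, validating the schema; returns TwinPair records.

    Raises :class:`SchemaError` naming the missing column or the offending
    row (1-based, excluding the header) for malformed values.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError("cohort file is empty (header required)") from exc
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file missing required column(s): {', '.join(missing)}")
    bad = ~df["zygosity"].isin(["MZ", "DZ"])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise SchemaError(f"row {row}: zygosity {df['zygosity'].iloc[row - 1]!r} outside {{MZ, DZ}}")
    out = {}
    for col in df.columns:
        try:
            if col in _INT_COLUMNS:
                out[col] = df[col].astype(int)
            elif col in _BOOL_COLUMNS:
                mapped = df[col].map({"True": True, "False": False})
                if mapped.isna().any():
                    row = int(np.flatnonzero(mapped.isna().to_numpy())[0]) + 1
                    raise SchemaError(f"row {row}: column {col!r} must be True/False")
                out[col] = mapped.astype(bool)
            elif col in ("zygosity", "sex"):
                out[col] = df[col]
            else:
                out[col] = df[col].astype(float)
        except ValueError as exc:
            raise SchemaError(f"column {col!r}: {exc}") from exc
    return frame_to_pairs(pd.DataFrame(out))


# ---------------------------------------------------------------------------
# pair-level simulators for twin variance-component experiments


def _pairs_frame(n_mz, n_dz, t1, t2, moderator=None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "zygosity": np.repeat(["MZ", "DZ"], [n_mz, n_dz]),
            "trait1": t1,
            "trait2": t2,
        }
    )
    if moderator is not None:
        df["moderator"] = moderator
    return df


def simulate_twin_pairs(n_mz: int, n_dz: int, r_mz: float, r_dz: float, mean: float = 0.0, sd: float = 1.0, seed: int = 0) -> pd.DataFrame:
    """Bivariate-normal twin pairs with given MZ and DZ correlations."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out1, out2 = [], []
    for n, r in ((n_mz, r_mz), (n_dz, r_dz)):
        z1 = rng.normal(size=n)
        z2 = r * z1 + np.sqrt(1.0 - r**2) * rng.normal(size=n)
        out1.append(mean + sd * z1)
        out2.append(mean + sd * z2)
    return _pairs_frame(n_mz, n_dz, np.concatenate(out1), np.concatenate(out2))


def simulate_ae_pairs(n_mz: int, n_dz: int, a2_share: float, total_var: float = 1.0, mean: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Twin pairs generated under the AE model with a given standardized
    additive-genetic share (A shared 1.0 MZ / 0.5 DZ; E independent)."""
    if not 0.0 <= a2_share <= 1.0:
        raise DomainError("a2_share must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    a = np.sqrt(a2_share * total_var)
    e = np.sqrt((1.0 - a2_share) * total_var)
    parts1, parts2 = [], []
    for n, share in ((n_mz, 1.0), (n_dz, 0.5)):
        fam = rng.normal(size=n)
        w_f, w_i = np.sqrt(share), np.sqrt(1.0 - share)
        a1 = fam if share == 1.0 else w_f * fam + w_i * rng.normal(size=n)
        a2c = fam if share == 1.0 else w_f * fam + w_i * rng.normal(size=n)
        parts1.append(mean + a * a1 + e * rng.normal(size=n))
        parts2.append(mean + a * a2c + e * rng.normal(size=n))
    return _pairs_frame(n_mz, n_dz, np.concatenate(parts1), np.concatenate(parts2))


def simulate_gxe_pairs(
    n_mz: int,
    n_dz: int,
    a0: float,
    e0: float,
    beta_a: float = 0.0,
    beta_e: float = 0.0,
    mean: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Twin pairs with A/E path moderation by a family-level standard-normal
    moderator M: trait = (a0 + beta_a*M)*A + (e0 + beta_e*M)*E + mean."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    t1, t2, mods = [], [], []
    for n, share in ((n_mz, 1.0), (n_dz, 0.5)):
        m = rng.normal(size=n)
        fam = rng.normal(size=n)
        w_f, w_i = np.sqrt(share), np.sqrt(1.0 - share)
        a1 = fam if share == 1.0 else w_f * fam + w_i * rng.normal(size=n)
        a2c = fam if share == 1.0 else w_f * fam + w_i * rng.normal(size=n)
        a_m = a0 + beta_a * m
        e_m = e0 + beta_e * m
        t1.append(mean + a_m * a1 + e_m * rng.normal(size=n))
        t2.append(mean + a_m * a2c + e_m * rng.normal(size=n))
        mods.append(m)
    return _pairs_frame(n_mz, n_dz, np.concatenate(t1), np.concatenate(t2), np.concatenate(mods))
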