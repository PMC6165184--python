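"""Packaged example dataset: the serum PTH / 25-hydroxyvitamin D instrument
tables from a published two-sample MR study of Alzheimer's disease.

The fixture reproduces that study's instrument table verbatim: five SNPs for
serum parathyroid hormone (S-PTH, exposure effects in ln-pg/mL) and seven
for serum 25-hydroxyvitamin D (S-25OHD, ln-nmol/L; one SNP reported per SD
of the standardized ln-trait), each with its association with Alzheimer's
disease (log odds ratios from a 17,008-case / 37,154-control GWAS
meta-analysis). rs10745742 was absent from the outcome dataset, so
rs1968487 (r2 = 1.0) serves as its proxy. Both exposures use an SD of 0.33
ln-units for per-SD reporting. The tables print only the exposure-increasing
effect allele, so harmonization runs in pre-oriented mode.
"""

from __future__ import annotations

from importlib import resources

from .instruments import (
    InstrumentSet,
    LdInfo,
    Unit,
    convert_units,
    filter_instruments,
    harmonize,
    read_proxy_map,
    read_summary_table,
    substitute_proxy,
)

__all__ = ["fixture_path", "fixture_paths", "SD_SCALE", "load_pth_ad",
           "load_vitd_ad", "prepare_instruments"]

#: SD of the ln-transformed exposures (ln-pg/mL for S-PTH, ln-nmol/L for
#: S-25OHD), from a population-based cohort; used to report per-SD effects.
SD_SCALE = 0.33

_FILES = {
    "pth_exposure": "pth_exposure.tsv",
    "vitd_exposure": "vitd_exposure.tsv",
    "ad_outcome": "ad_outcome.tsv",
    "proxy_map": "proxy_map.tsv",
    "ld_pairs": "ld_pairs.tsv",
}


def fixture_path(name: str):
    """Filesystem path of one packaged fixture file (see ``fixture_paths``)."""
    if name not in _FILES:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(_FILES)}")
    return resources.files("mrkit.data").joinpath(_FILES[name])


def fixture_paths() -> dict:
    """All packaged fixture files, keyed by short name."""
    return {k: fixture_path(k) for k in _FILES}


def prepare_instruments(
    exposure_path,
    outcome_path,
    *,
    exposure_name: str,
    sd_scale: float = SD_SCALE,
    proxy_path=None,
    ld_path=None,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.05,
    min_proxy_r2: float = 0.8,
    log=None,
) -> InstrumentSet:
    """Full preparation pipeline: read, filter, proxy, unit-convert,
    harmonize.

    ``log`` may be a list; human-readable lines describing every SNP-level
    decision (rows read, SNPs dropped, proxies applied, unit conversions)
    are appended to it.
    """
    say = (log.append if log is not None else (lambda _msg: None))
    exposure = read_summary_table(exposure_path, role="exposure")
    outcome = read_summary_table(outcome_path, role="outcome")
    say(f"read {len(exposure)} exposure rows from {exposure_path}")
    say(f"read {len(outcome)} outcome rows from {outcome_path}")

    ld = LdInfo.from_file(ld_path) if ld_path else LdInfo()
    before = {a.rsid for a in exposure}
    exposure = filter_instruments(exposure, p_threshold, ld, r2_threshold)
    for rsid in sorted(before - {a.rsid for a in exposure}):
        say(f"dropped {rsid}: failed p < {p_threshold} or LD pruning "
            f"(r2 >= {r2_threshold})")

    if proxy_path:
        proxy_map = read_proxy_map(proxy_path)
        outcome = substitute_proxy(outcome, proxy_map, min_r2=min_proxy_r2)
        for target, (proxy, r2) in proxy_map.items():
            say(f"proxy: {proxy} (r2 = {r2}) used for {target} in outcome data")

    converted = []
    for a in exposure:
        if a.unit is Unit.SD_OF_LN_TRAIT:
            say(f"unit conversion: {a.rsid} beta {a.beta} -> "
                f"{a.beta * sd_scale} (x sd_scale {sd_scale}, SD -> ln units)")
            a = convert_units(a, sd_scale)
        converted.append(a)

    iset = harmonize(
        converted, outcome, exposure_name=exposure_name, sd_scale=sd_scale
    )
    for inst in iset:
        flip = " (orientation flipped)" if inst.beta_exp < 0 else ""
        say(f"harmonized {inst.rsid}: beta_exp {inst.beta_exp}, "
            f"beta_out {inst.beta_out}{flip}"
            + (f", proxied by {inst.proxied_by}" if inst.proxied_by else ""))
    return iset


def load_pth_ad(log=None) -> InstrumentSet:
    """The 5 serum-PTH instruments harmonized against Alzheimer's disease."""
    return prepare_instruments(
        fixture_path("pth_exposure"),
        fixture_path("ad_outcome"),
        exposure_name="S-PTH",
        proxy_path=fixture_path("proxy_map"),
        ld_path=fixture_path("ld_pairs"),
        log=log,
    )


def load_vitd_ad(log=None) -> InstrumentSet:
    """The 7 serum-25OHD instruments harmonized against Alzheimer's disease.

    Applies the rs1968487 proxy substitution and converts rs117913124 from
    SD-of-ln units into ln-nmol/L (x 0.33).
    """
    return prepare_instruments(
        fixture_path("vitd_exposure"),
        fixture_path("ad_outcome"),
        exposure_name="S-25OHD",
        proxy_path=fixture_path("proxy_map"),
        ld_path=fixture_path("ld_pairs"),
        log=log,
    )
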