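"""Reading, validation, harmonization and unit conversion of GWAS
summary statistics for two-sample Mendelian randomization.

A two-sample MR analysis starts from two per-SNP association tables — one
against the exposure (here a serum biomarker on the natural-log scale), one
against a disease outcome (log odds ratios) — and must align them so that,
for every instrument, both effect sizes refer to the same allele on the same
strand, with the exposure effect oriented to the exposure-increasing allele.
This module provides the data containers (:class:`SnpAssociation`,
:class:`HarmonizedInstrument`, :class:`InstrumentSet`, :class:`LdInfo`) and
the operations that turn raw tables into an analysis-ready instrument set:

* :func:`read_summary_table` / :func:`write_summary_table` — delimited I/O
  with a configurable column mapping;
* :func:`filter_instruments` — genome-wide significance and LD pruning;
* :func:`substitute_proxy` — replace an instrument missing from the outcome
  dataset by a high-r2 proxy;
* :func:`convert_units` — rescale an exposure effect reported per standard
  deviation of the ln-trait into ln-trait units;
* :func:`harmonize` — allele/strand alignment producing an
  :class:`InstrumentSet`.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import (
    ConfigError,
    HarmonizationError,
    ProxyError,
    SummaryTableError,
    ValidationError,
)

__all__ = [
    "Unit",
    "SnpAssociation",
    "HarmonizedInstrument",
    "InstrumentSet",
    "LdInfo",
    "DEFAULT_DIALECT",
    "read_summary_table",
    "write_summary_table",
    "read_proxy_map",
    "filter_instruments",
    "substitute_proxy",
    "convert_units",
    "harmonize",
    "flip_association",
]

#: Smallest positive double; p-values whose text representation is a positive
#: number too small for IEEE doubles (e.g. 4.74e-343) are clamped here so the
#: (0, 1] invariant survives underflow.
_TINY_P = 5e-324

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})


class Unit(str, Enum):
    """Scale on which a per-allele effect size is expressed."""

    LN_TRAIT = "ln_trait"  # per natural-log unit of the trait
    SD_OF_LN_TRAIT = "sd_of_ln_trait"  # per SD of the standardized ln-trait
    LOG_ODDS = "log_odds"  # log odds ratio (binary outcome)


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's association with one trait, as exported by a GWAS.

    Parameters
    ----------
    rsid : str
        Variant identifier.
    chrom : str
        Chromosome label (kept as text: "X", "23", ...).
    effect_allele : str
        Allele the effect size refers to.
    beta : float
        Signed per-allele effect on the trait, in ``unit`` units.
    se : float
        Standard error of ``beta``; must be positive.
    pvalue : float
        Association p-value in (0, 1].
    unit : Unit
        Scale of ``beta``.
    other_allele : str, optional
        The non-effect allele; some published instrument tables omit it,
        which restricts harmonization to pre-oriented mode.
    eaf : float, optional
        Effect-allele frequency in (0, 1); needed only to resolve
        palindromic variants.
    nearby_gene : str, optional
        Annotation only, never used in computation.
    proxied_by : str, optional
        Set by :func:`substitute_proxy` when this record's statistics were
        taken from a proxy variant.
    """

    rsid: str
    chrom: str
    effect_allele: str
    beta: float
    se: float
    pvalue: float
    unit: Unit = Unit.LN_TRAIT
    other_allele: str | None = None
    eaf: float | None = None
    nearby_gene: str | None = None
    proxied_by: str | None = None

    def __post_init__(self):
        if not self.rsid:
            raise ValidationError("rsid must be non-empty")
        if not (self.se > 0):
            raise ValidationError(f"{self.rsid}: se must be > 0, got {self.se}")
        if not (0 < self.pvalue <= 1):
            raise ValidationError(
                f"{self.rsid}: pvalue must be in (0, 1], got {self.pvalue}"
            )
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValidationError(
                f"{self.rsid}: eaf must be in (0, 1), got {self.eaf}"
            )
        if not math.isfinite(self.beta):
            raise ValidationError(f"{self.rsid}: beta must be finite")

    @property
    def is_palindromic(self) -> bool:
        """True when the allele pair is strand-ambiguous (A/T or C/G)."""
        if self.other_allele is None:
            return False
        return {self.effect_allele, self.other_allele} in _PALINDROMIC_PAIRS


def flip_association(assoc: SnpAssociation) -> SnpAssociation:
    """Re-express an association relative to the other allele.

    Negates ``beta``, swaps the allele labels and reflects the effect-allele
    frequency; the standard error, p-value and unit are untouched. Applying
    the flip twice returns the original record (involution).
    """
    return replace(
        assoc,
        beta=-assoc.beta,
        effect_allele=assoc.other_allele if assoc.other_allele is not None else assoc.effect_allele,
        other_allele=assoc.effect_allele if assoc.other_allele is not None else None,
        eaf=None if assoc.eaf is None else 1.0 - assoc.eaf,
    )


@dataclass(frozen=True)
class HarmonizedInstrument:
    """A SNP with exposure and outcome effects on a common, exposure-
    increasing allele.

    ``beta_exp`` is in ln-trait units per allele and is non-negative by
    construction; ``beta_out`` is the log odds ratio of the outcome per copy
    of the same allele. Standard errors are never altered by orientation.
    """

    rsid: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    proxied_by: str | None = None

    def __post_init__(self):
        if self.beta_exp < 0:
            raise ValidationError(
                f"{self.rsid}: beta_exp must be >= 0 after orientation"
            )
        if not (self.se_exp > 0 and self.se_out > 0):
            raise ValidationError(f"{self.rsid}: standard errors must be > 0")


@dataclass(frozen=True)
class InstrumentSet:
    """A named exposure's harmonized instruments plus its SD scale.

    ``sd_scale`` is the standard deviation of the ln-transformed exposure in
    ln-units per SD; estimators multiply per-ln-unit causal effects by it to
    report effects per SD of the exposure.
    """

    exposure_name: str
    sd_scale: float
    instruments: tuple[HarmonizedInstrument, ...]

    def __post_init__(self):
        object.__setattr__(self, "instruments", tuple(self.instruments))
        if not (self.sd_scale > 0):
            raise ValidationError("sd_scale must be > 0")
        if len(self.instruments) < 1:
            raise ValidationError("at least one instrument required")
        rsids = [i.rsid for i in self.instruments]
        if len(set(rsids)) != len(rsids):
            raise ValidationError("duplicate rsids in instrument set")

    def __len__(self) -> int:
        return len(self.instruments)

    def __iter__(self):
        return iter(self.instruments)

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(i.rsid for i in self.instruments)

    def drop(self, rsid: str) -> "InstrumentSet":
        """A new set without the named instrument."""
        kept = [i for i in self.instruments if i.rsid != rsid]
        if len(kept) == len(self.instruments):
            raise KeyError(rsid)
        return InstrumentSet(self.exposure_name, self.sd_scale, tuple(kept))

    def arrays(self):
        """(beta_exp, se_exp, beta_out, se_out) as float lists, in order."""
        return (
            [i.beta_exp for i in self.instruments],
            [i.se_exp for i in self.instruments],
            [i.beta_out for i in self.instruments],
            [i.se_out for i in self.instruments],
        )


class LdInfo:
    """Pairwise linkage-disequilibrium r2 between instruments.

    Stores a symmetric mapping from unordered rsid pairs to r2 in [0, 1].
    An empty ``LdInfo`` means all pairs are treated as independent.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._r2: dict[frozenset, float] = {}
        for (a, b), r2 in (pairs or {}).items():
            self.add(a, b, r2)

    def add(self, rsid_a: str, rsid_b: str, r2: float) -> None:
        if not (0 <= r2 <= 1):
            raise ValidationError(f"r2 must be in [0, 1], got {r2}")
        if rsid_a == rsid_b:
            raise ValidationError("LD pair must involve two distinct rsids")
        self._r2[frozenset((rsid_a, rsid_b))] = float(r2)

    def get(self, rsid_a: str, rsid_b: str, default: float = 0.0) -> float:
        return self._r2.get(frozenset((rsid_a, rsid_b)), default)

    def pairs(self):
        """Deterministically ordered (rsid_a, rsid_b, r2) triples."""
        out = [(*sorted(k), v) for k, v in self._r2.items()]
        return sorted(out)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_file(cls, path) -> "LdInfo":
        """Read a delimited file with columns rsid1, rsid2, r2."""
        ld = cls()
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter=_sniff_delimiter(path))
            for col in ("rsid1", "rsid2", "r2"):
                if reader.fieldnames is None or col not in reader.fieldnames:
                    raise ConfigError(f"{path}: missing column '{col}'")
            for row in reader:
                ld.add(row["rsid1"], row["rsid2"], float(row["r2"]))
        return ld


# ---------------------------------------------------------------------------
# Delimited I/O

#: Canonical field -> default column name in input files.
DEFAULT_DIALECT: dict[str, str] = {
    "rsid": "rsid",
    "chrom": "chr",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pval",
    "unit": "unit",
    "nearby_gene": "gene",
}

_MANDATORY = ("rsid", "chrom", "effect_allele", "beta", "se", "pvalue")


def _sniff_delimiter(path) -> str:
    with open(path, newline="") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _parse_float(text: str, what: str):
    try:
        value = float(text)
    except (TypeError, ValueError):
        raise ValueError(f"non-numeric {what}: {text!r}")
    return value


def read_summary_table(
    path,
    role: str,
    dialect: Mapping[str, str] | None = None,
) -> list[SnpAssociation]:
    """Read a delimited per-SNP summary-statistics table.

    Parameters
    ----------
    path : path-like
        Tab- or comma-separated file with a header row.
    role : {"exposure", "outcome"}
        Determines the default effect-size unit (ln-trait for exposures,
        log-odds for outcomes) and which units are legal.
    dialect : mapping, optional
        Overrides for :data:`DEFAULT_DIALECT`, mapping canonical field names
        (``rsid``, ``chrom``, ``effect_allele``, ``other_allele``, ``eaf``,
        ``beta``, ``se``, ``pvalue``, ``unit``, ``nearby_gene``) to the
        column names actually present in the file.

    Returns
    -------
    list of SnpAssociation
        One record per data row, in file order.

    Raises
    ------
    ConfigError
        A mandatory mapped column is absent from the header.
    SummaryTableError
        Any row has a missing or non-numeric beta/se, an invalid value, or
        a duplicate rsid; the error lists every offending line number.
    """
    if role not in ("exposure", "outcome"):
        raise ConfigError(f"role must be 'exposure' or 'outcome', got {role!r}")
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        unknown = set(dialect) - set(DEFAULT_DIALECT)
        if unknown:
            raise ConfigError(f"unknown dialect fields: {sorted(unknown)}")
        cols.update(dialect)

    default_unit = Unit.LN_TRAIT if role == "exposure" else Unit.LOG_ODDS
    delim = _sniff_delimiter(path)
    records: list[SnpAssociation] = []
    row_errors: list[tuple[int, str]] = []
    seen: dict[str, int] = {}

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        for fld in _MANDATORY:
            if cols[fld] not in header:
                raise ConfigError(
                    f"{path}: missing mandatory column '{cols[fld]}' (field {fld})"
                )
        has = {f: cols[f] in header for f in cols}

        for lineno, row in enumerate(reader, start=2):
            try:
                rsid = (row[cols["rsid"]] or "").strip()
                if not rsid:
                    raise ValueError("empty rsid")
                if rsid in seen:
                    raise ValueError(
                        f"duplicate rsid {rsid} (first seen line {seen[rsid]})"
                    )
                raw_beta = (row[cols["beta"]] or "").strip()
                raw_se = (row[cols["se"]] or "").strip()
                if raw_beta == "" or raw_se == "":
                    raise ValueError("missing beta or se")
                beta = _parse_float(raw_beta, "beta")
                se = _parse_float(raw_se, "se")
                raw_p = (row[cols["pvalue"]] or "").strip()
                pvalue = _parse_float(raw_p, "pvalue")
                if pvalue == 0.0 and not raw_p.lstrip("+").startswith(("0", ".")):
                    # positive literal below double-precision range
                    pvalue = _TINY_P
                eaf = None
                if has["eaf"]:
                    raw = (row.get(cols["eaf"]) or "").strip()
                    eaf = _parse_float(raw, "eaf") if raw else None
                other = None
                if has["other_allele"]:
                    other = (row.get(cols["other_allele"]) or "").strip() or None
                unit = default_unit
                if has["unit"]:
                    raw = (row.get(cols["unit"]) or "").strip()
                    if raw:
                        try:
                            unit = Unit(raw)
                        except ValueError:
                            raise ValueError(f"unknown unit {raw!r}")
                if role == "outcome" and unit is not Unit.LOG_ODDS:
                    raise ValueError(f"outcome rows must be log_odds, got {unit.value}")
                if role == "exposure" and unit is Unit.LOG_ODDS:
                    raise ValueError("exposure rows cannot be log_odds")
                gene = None
                if has["nearby_gene"]:
                    gene = (row.get(cols["nearby_gene"]) or "").strip() or None
                rec = SnpAssociation(
                    rsid=rsid,
                    chrom=(row[cols["chrom"]] or "").strip(),
                    effect_allele=(row[cols["effect_allele"]] or "").strip(),
                    other_allele=other,
                    eaf=eaf,
                    beta=beta,
                    se=se,
                    pvalue=pvalue,
                    unit=unit,
                    nearby_gene=gene,
                )
            except (ValueError, ValidationError) as exc:
                row_errors.append((lineno, str(exc)))
                continue
            seen[rsid] = lineno
            records.append(rec)

    if row_errors:
        raise SummaryTableError(path, row_errors)
    return records


def write_summary_table(assocs: Sequence[SnpAssociation], path, sep: str = "\t") -> None:
    """Write records in the default dialect at full double precision.

    The written file round-trips through :func:`read_summary_table` with all
    numeric fields bit-identical (floats are serialized with ``repr``).
    """
    path = Path(path)
    fields = ["rsid", "chr", "effect_allele", "other_allele", "eaf", "beta",
              "se", "pval", "unit", "gene"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep, lineterminator="\n")
        writer.writerow(fields)
        for a in assocs:
            writer.writerow([
                a.rsid,
                a.chrom,
                a.effect_allele,
                a.other_allele or "",
                "" if a.eaf is None else repr(a.eaf),
                repr(a.beta),
                repr(a.se),
                repr(a.pvalue),
                a.unit.value,
                a.nearby_gene or "",
            ])


def read_proxy_map(path) -> dict[str, tuple[str, float]]:
    """Read a delimited proxy file with columns target_rsid, proxy_rsid, r2."""
    out: dict[str, tuple[str, float]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=_sniff_delimiter(path))
        for col in ("target_rsid", "proxy_rsid", "r2"):
            if reader.fieldnames is None or col not in reader.fieldnames:
                raise ConfigError(f"{path}: missing column '{col}'")
        for row in reader:
            out[row["target_rsid"].strip()] = (
                row["proxy_rsid"].strip(),
                float(row["r2"]),
            )
    return out


# ---------------------------------------------------------------------------
# Instrument selection

def filter_instruments(
    assocs: Sequence[SnpAssociation],
    p_threshold: float = 5e-8,
    ld: LdInfo | None = None,
    r2_threshold: float = 0.05,
) -> list[SnpAssociation]:
    """Keep genome-wide-significant, mutually independent instruments.

    A record survives when its p-value is strictly below ``p_threshold``.
    Among any pair of survivors with r2 >= ``r2_threshold`` only one is
    retained: the one with the smaller p-value, ties broken by smaller
    standard error, then lexicographically smaller rsid. Input order is
    preserved; the result is always a subset of the input and the operation
    is idempotent.
    """
    if not (0 < p_threshold < 1):
        raise ConfigError(f"p_threshold must be in (0, 1), got {p_threshold}")
    if not (0 < r2_threshold <= 1):
        raise ConfigError(f"r2_threshold must be in (0, 1], got {r2_threshold}")
    kept = [a for a in assocs if a.pvalue < p_threshold]
    if ld is None or len(ld) == 0:
        return kept

    def _loses(a: SnpAssociation, b: SnpAssociation) -> SnpAssociation:
        ka = (a.pvalue, a.se, a.rsid)
        kb = (b.pvalue, b.se, b.rsid)
        return a if ka > kb else b

    removed: set[str] = set()
    changed = True
    while changed:
        changed = False
        by_rsid = {a.rsid: a for a in kept if a.rsid not in removed}
        for ra, rb, r2 in ld.pairs():
            if r2 >= r2_threshold and ra in by_rsid and rb in by_rsid:
                removed.add(_loses(by_rsid[ra], by_rsid[rb]).rsid)
                changed = True
                break
    return [a for a in kept if a.rsid not in removed]


def substitute_proxy(
    assocs: Sequence[SnpAssociation],
    proxy_map: Mapping[str, tuple[str, float]],
    min_r2: float = 0.8,
) -> list[SnpAssociation]:
    """Stand in a high-LD proxy for instruments missing from a dataset.

    For each ``target_rsid -> (proxy_rsid, r2)`` entry, the proxy's summary
    statistics are assigned to the target rsid with ``proxied_by`` recording
    the substitution. If the target already has a record it is replaced in
    place; otherwise the proxy's own record is relabeled in place. Unmapped
    records pass through unchanged.

    Raises
    ------
    ProxyError
        A proxy's r2 falls below ``min_r2``, or the proxy rsid is absent
        from ``assocs``.
    """
    for target, (proxy, r2) in proxy_map.items():
        if r2 < min_r2:
            raise ProxyError(
                f"proxy {proxy} for {target} refused: r2 {r2} < min_r2 {min_r2}"
            )
    by_rsid = {a.rsid: i for i, a in enumerate(assocs)}
    out = list(assocs)
    consumed: list[int] = []
    for target, (proxy, r2) in proxy_map.items():
        if proxy not in by_rsid:
            raise ProxyError(f"proxy {proxy} for {target} not found in data")
        stats = assocs[by_rsid[proxy]]
        new = replace(stats, rsid=target, proxied_by=proxy)
        if target in by_rsid:
            out[by_rsid[target]] = new
            consumed.append(by_rsid[proxy])
        else:
            out[by_rsid[proxy]] = new
    return [a for i, a in enumerate(out) if i not in consumed]


def convert_units(assoc: SnpAssociation, sd_scale: float) -> SnpAssociation:
    """Convert an exposure effect from SD-of-ln-trait units to ln-trait units.

    Both the effect size and its standard error are multiplied by
    ``sd_scale`` (the SD of the ln-transformed trait), so the z-score and
    p-value are unchanged. Calling this on a record already in ln-trait
    units warns and returns it untouched (idempotence by unit flag).
    """
    if not (sd_scale > 0):
        raise ConfigError(f"sd_scale must be > 0, got {sd_scale}")
    if assoc.unit is Unit.LN_TRAIT:
        warnings.warn(
            f"{assoc.rsid}: already in ln-trait units; convert_units is a no-op",
            stacklevel=2,
        )
        return assoc
    if assoc.unit is not Unit.SD_OF_LN_TRAIT:
        raise ConfigError(
            f"{assoc.rsid}: cannot unit-convert a {assoc.unit.value} association"
        )
    return replace(
        assoc,
        beta=assoc.beta * sd_scale,
        se=assoc.se * sd_scale,
        unit=Unit.LN_TRAIT,
    )


# ---------------------------------------------------------------------------
# Harmonization

def _allele_sign(exp: SnpAssociation, out: SnpAssociation) -> int:
    """+1 if the outcome effect allele is the exposure effect allele,
    -1 if it is the other allele; strand complement attempted before
    declaring a mismatch. Non-palindromic context only."""
    ea_e, oa_e = exp.effect_allele, exp.other_allele
    ea_o, oa_o = out.effect_allele, out.other_allele
    if oa_o is not None and oa_e is not None:
        # both sides carry the full pair: require pair identity, on the
        # reported strand or its complement
        pair_e = {ea_e, oa_e}
        if {ea_o, oa_o} == pair_e:
            return 1 if ea_o == ea_e else -1
        comp_pair = {_COMPLEMENT.get(ea_o), _COMPLEMENT.get(oa_o)}
        if comp_pair == pair_e:
            return 1 if _COMPLEMENT.get(ea_o) == ea_e else -1
        raise HarmonizationError(
            f"{exp.rsid}: alleles irreconcilable "
            f"(exposure {ea_e}/{oa_e}, outcome {ea_o}/{oa_o})"
        )
    if ea_o == ea_e:
        return 1
    if oa_e is not None and ea_o == oa_e:
        return -1
    comp = _COMPLEMENT.get(ea_o)
    if comp == ea_e:
        return 1
    if oa_e is not None and comp == oa_e:
        return -1
    raise HarmonizationError(
        f"{exp.rsid}: alleles irreconcilable "
        f"(exposure {ea_e}/{oa_e}, outcome effect allele {ea_o})"
    )


def _palindromic_sign(
    exp: SnpAssociation,
    out: SnpAssociation,
    policy: str,
    eaf_tolerance: float,
) -> int | None:
    """Outcome-beta sign for a strand-ambiguous SNP; None means drop."""
    if policy == "drop":
        return None
    if policy == "trust":
        # same-strand assumption: letters decide
        return 1 if out.effect_allele == exp.effect_allele else -1
    # eaf_infer
    if exp.eaf is None or out.eaf is None:
        raise HarmonizationError(
            f"{exp.rsid}: palindromic SNP needs eaf on both sides for eaf_infer"
        )
    if abs(exp.eaf - 0.5) < eaf_tolerance or abs(out.eaf - 0.5) < eaf_tolerance:
        raise HarmonizationError(
            f"{exp.rsid}: palindromic SNP too close to eaf 0.5 to orient "
            f"(tolerance {eaf_tolerance})"
        )
    letter = 1 if out.effect_allele == exp.effect_allele else -1
    same_side = (exp.eaf < 0.5) == (out.eaf < 0.5)
    # a strand flip on a palindrome swaps the allele letters, so if the
    # frequencies land on opposite sides of 0.5 the letter decision reverses
    return letter if same_side else -letter


def harmonize(
    exposure: Sequence[SnpAssociation],
    outcome: Sequence[SnpAssociation],
    palindrome_policy: str = "eaf_infer",
    eaf_tolerance: float = 0.08,
    *,
    exposure_name: str = "exposure",
    sd_scale: float = 1.0,
) -> InstrumentSet:
    """Align exposure and outcome effects to the exposure-increasing allele.

    For every exposure record (all must be in ln-trait units; convert SD-unit
    records first) the matching outcome record is located by rsid and the two
    effects are put on a common allele:

    * if the exposure beta is negative the exposure record is flipped to the
      other allele, and in consequence the outcome beta is re-signed too;
    * when both records carry full allele pairs, the outcome effect allele is
      compared with the oriented exposure effect allele, attempting a strand
      complement before declaring a mismatch;
    * when either side lacks the other allele (as in published instrument
      tables that print only the effect allele), harmonization runs in
      pre-oriented mode: the outcome beta is trusted to refer to the printed
      exposure effect allele;
    * palindromic (A/T, C/G) variants are handled per ``palindrome_policy``:
      ``drop`` excludes them, ``trust`` assumes both studies report the same
      strand, ``eaf_infer`` orients by comparing allele frequencies to 0.5
      and fails when either frequency is within ``eaf_tolerance`` of 0.5.

    Returns an :class:`InstrumentSet` whose ``beta_exp`` are all >= 0.

    Raises
    ------
    HarmonizationError
        An exposure rsid is missing from the outcome data (the error lists
        every missing rsid), an allele pair is irreconcilable, or a
        palindromic variant cannot be oriented.
    """
    if palindrome_policy not in ("drop", "eaf_infer", "trust"):
        raise ConfigError(f"unknown palindrome policy {palindrome_policy!r}")
    out_by_rsid = {a.rsid: a for a in outcome}
    missing = [a.rsid for a in exposure if a.rsid not in out_by_rsid]
    if missing:
        raise HarmonizationError(
            f"exposure rsids missing from outcome data: {', '.join(missing)}"
        )
    non_ln = [a.rsid for a in exposure if a.unit is not Unit.LN_TRAIT]
    if non_ln:
        raise HarmonizationError(
            "exposure records must be in ln-trait units before harmonization "
            f"(convert_units first): {', '.join(non_ln)}"
        )

    instruments: list[HarmonizedInstrument] = []
    for rec in exposure:
        out = out_by_rsid[rec.rsid]
        oriented = flip_association(rec) if rec.beta < 0 else rec
        flipped = rec.beta < 0

        full_alleles = oriented.other_allele is not None and out.effect_allele != ""
        if full_alleles and rec.is_palindromic:
            sign = _palindromic_sign(oriented, out, palindrome_policy, eaf_tolerance)
            if sign is None:
                continue
        elif full_alleles:
            sign = _allele_sign(oriented, out)
        else:
            # pre-oriented mode: outcome beta refers to the printed exposure
            # effect allele, so only an orientation flip re-signs it
            sign = -1 if flipped else 1
        instruments.append(
            HarmonizedInstrument(
                rsid=rec.rsid,
                beta_exp=oriented.beta,
                se_exp=oriented.se,
                beta_out=sign * out.beta,
                se_out=out.se,
                proxied_by=out.proxied_by,
            )
        )
    return InstrumentSet(exposure_name, sd_scale, tuple(instruments))
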