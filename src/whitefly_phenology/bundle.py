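"""Serialization of the full species parameter bundle.

A :class:`ModelBundle` collects every fitted temperature-response function
and distribution link needed to simulate the whitefly life cycle: Janisch
development curves and their links per immature stage, the shared-optimum
mortality parameters, the adult timing model with senescence/oviposition
links, the fecundity curve with its residual spread, the
fluctuating-temperature adjustment factors and the sex ratio.  Bundles are
stored as a single YAML file with one block per process; the packaged
default carries the published parameter values for
*Trialeurodes vaporariorum* on potato.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import yaml

from .distributions import DistributionLink
from .thermal import (
    AdjustmentFactors,
    AdultTimingParams,
    FecundityParams,
    JanischParams,
    MortalityParams,
)

__all__ = ["ModelBundle", "BundleError", "load_bundle", "save_bundle", "default_bundle"]

STAGES = ("egg", "nymph", "puparium")


class BundleError(ValueError):
    """A bundle file is missing or malforms a required block."""


@dataclass(frozen=True)
class ModelBundle:
    development: dict[str, JanischParams]
    dev_links: dict[str, DistributionLink]
    mortality: dict[str, MortalityParams]
    adult: AdultTimingParams
    senescence_link: DistributionLink
    oviposition_link: DistributionLink
    fecundity: FecundityParams
    fecundity_sigma: float
    adjustment: AdjustmentFactors = field(default_factory=AdjustmentFactors)
    sex_ratio: float = 0.5
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for table, what in ((self.development, "development"),
                            (self.dev_links, "dev_links"),
                            (self.mortality, "mortality")):
            missing = [s for s in STAGES if s not in table]
            if missing:
                raise BundleError(f"{what}: missing stage block(s) {missing}")
        if not 0.0 < self.sex_ratio < 1.0:
            raise BundleError("sex_ratio must lie in (0, 1)")
        if not self.fecundity_sigma >= 0:
            raise BundleError("fecundity_sigma must be non-negative")


def _link_to_dict(link: DistributionLink) -> dict:
    return {"family": link.family, "delta": link.delta}


def _link_from_dict(d: dict, where: str) -> DistributionLink:
    try:
        return DistributionLink(family=d["family"], delta=float(d["delta"]))
    except (KeyError, TypeError, ValueError) as e:
        raise BundleError(f"{where}: invalid distribution link ({e})") from e


def bundle_to_dict(b: ModelBundle) -> dict:
    return {
        "species": b.metadata.get("species", ""),
        "metadata": b.metadata,
        "development": {
            s: {"d_min": p.d_min, "t_opt": p.t_opt, "k": p.k,
                "link": _link_to_dict(b.dev_links[s])}
            for s, p in b.development.items()
        },
        "mortality": {
            s: {"h": p.h, "b": p.b, "t_opt": p.t_opt}
            for s, p in b.mortality.items()
        },
        "adult": {
            "intercept": b.adult.intercept,
            "slope": b.adult.slope,
            "factor_female": b.adult.factor_female,
            "factor_male": b.adult.factor_male,
            "senescence_link": _link_to_dict(b.senescence_link),
            "oviposition_link": _link_to_dict(b.oviposition_link),
        },
        "fecundity": {
            "h": b.fecundity.h, "tl": b.fecundity.tl,
            "bl": b.fecundity.bl, "bh": b.fecundity.bh,
            "multiplier": b.fecundity.multiplier,
            "sigma_ln": b.fecundity_sigma,
        },
        "adjustment": {
            "mortality_b": b.adjustment.mortality_b,
            "adult_time": b.adjustment.adult_time,
            "fecundity": b.adjustment.fecundity,
        },
        "sex_ratio": b.sex_ratio,
    }


def bundle_from_dict(doc: dict) -> ModelBundle:
    if not isinstance(doc, dict):
        raise BundleError("bundle document is not a mapping")

    def block(name):
        if name not in doc:
            raise BundleError(f"missing required block: {name!r}")
        return doc[name]

    dev_raw = block("development")
    development, dev_links = {}, {}
    for s in STAGES:
        if s not in dev_raw:
            raise BundleError(f"development: missing stage {s!r}")
        d = dev_raw[s]
        try:
            development[s] = JanischParams(
                d_min=float(d["d_min"]), t_opt=float(d["t_opt"]),
                k=float(d["k"]), stage=s)
        except (KeyError, TypeError, ValueError) as e:
            raise BundleError(f"development/{s}: {e}") from e
        dev_links[s] = _link_from_dict(d.get("link", {}), f"development/{s}/link")

    mort_raw = block("mortality")
    mortality = {}
    for s in STAGES:
        if s not in mort_raw:
            raise BundleError(f"mortality: missing stage {s!r}")
        d = mort_raw[s]
        try:
            mortality[s] = MortalityParams(
                h=float(d["h"]), b=float(d["b"]),
                t_opt=float(d["t_opt"]), stage=s)
        except (KeyError, TypeError, ValueError) as e:
            raise BundleError(f"mortality/{s}: {e}") from e

    a = block("adult")
    try:
        adult = AdultTimingParams(
            intercept=float(a["intercept"]), slope=float(a["slope"]),
            factor_female=float(a.get("factor_female", 0.0)),
            factor_male=float(a.get("factor_male", 0.0)))
    except (KeyError, TypeError, ValueError) as e:
        raise BundleError(f"adult: {e}") from e
    sen_link = _link_from_dict(a.get("senescence_link", {}), "adult/senescence_link")
    ovi_link = _link_from_dict(a.get("oviposition_link", {}), "adult/oviposition_link")

    f = block("fecundity")
    try:
        fecundity = FecundityParams(
            h=float(f["h"]), tl=float(f["tl"]), bl=float(f["bl"]),
            bh=float(f["bh"]), multiplier=float(f.get("multiplier", 1.0)))
        sigma = float(f.get("sigma_ln", 0.0))
    except (KeyError, TypeError, ValueError) as e:
        raise BundleError(f"fecundity: {e}") from e

    adj_raw = doc.get("adjustment", {})
    adjustment = AdjustmentFactors(
        mortality_b=float(adj_raw.get("mortality_b", 1.3)),
        adult_time=float(adj_raw.get("adult_time", 2.0)),
        fecundity=float(adj_raw.get("fecundity", 4.0)))

    return ModelBundle(
        development=development, dev_links=dev_links, mortality=mortality,
        adult=adult, senescence_link=sen_link, oviposition_link=ovi_link,
        fecundity=fecundity, fecundity_sigma=sigma, adjustment=adjustment,
        sex_ratio=float(doc.get("sex_ratio", 0.5)),
        metadata=doc.get("metadata", {}) or {})


def save_bundle(bundle: ModelBundle, path) -> None:
    Path(path).write_text(yaml.safe_dump(bundle_to_dict(bundle), sort_keys=False))


def load_bundle(path) -> ModelBundle:
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as e:
        raise BundleError(f"unparseable bundle file: {e}") from e
    return bundle_from_dict(doc)


def bundle_hash(path) -> str:
    """Short SHA-256 digest of a bundle file, for run logging."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def default_bundle() -> ModelBundle:
    """The packaged parameter bundle for *T. vaporariorum*."""
    ref = resources.files("whitefly_phenology").joinpath("data/default_bundle.yaml")
    return bundle_from_dict(yaml.safe_load(ref.read_text()))
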