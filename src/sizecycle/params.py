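"""Parameter and genome configuration containers.

All quantities use the model's arbitrary units: AU for molecule number,
AV for cell volume and an arbitrary time unit.  Bimolecular association
constants carry units of AV per AU per time and are divided by the total
cell volume inside the rate laws; first-order constants are per time.

Parameter files are flat ``key: value`` YAML mappings whose keys are the
model's rate-constant symbols (``kGiTmAs``, ``kWhiSbfAs``, ...), plus the
gene-copy configuration under the same symbols (``GDt``, ``GCN``, ...).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "GenomeConfig",
    "ExpressionParams",
    "DilutionParams",
    "TitrationParams",
    "load_params",
    "save_params",
    "default_params",
    "default_genome",
    "scale_growth",
]


@dataclass
class GenomeConfig:
    """Gene-copy configuration of one cell.

    GDt : total number of size-dependent genes (the bulk of the genome).
    GIt : total number of size-independent genes (equals GWt: the Whi5
          gene is the only size-independent gene in the model).
    GCN : overall gene copy number (ploidy).
    GWt : WHI5 copy number.
    GCt : CLN3 copy number.
    NSt : number of genomic SBF-binding sites (titration model only).

    All counts double at Start and halve at division.
    """

    GDt: float = 200.0
    GIt: float = 1.0
    GCN: float = 1.0
    GWt: float = 1.0
    GCt: float = 1.0
    NSt: float = 0.0

    def __post_init__(self) -> None:
        for name in ("GDt", "GIt", "GCN", "GWt", "GCt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"gene count {name} must be > 0")
        if self.NSt < 0:
            raise ValueError("NSt must be >= 0")

    def doubled(self) -> "GenomeConfig":
        """Genome after replication (Start): every count doubles."""
        return GenomeConfig(
            GDt=2 * self.GDt, GIt=2 * self.GIt, GCN=2 * self.GCN,
            GWt=2 * self.GWt, GCt=2 * self.GCt, NSt=2 * self.NSt,
        )

    def halved(self) -> "GenomeConfig":
        """Genome after division: every count halves."""
        return GenomeConfig(
            GDt=self.GDt / 2, GIt=self.GIt / 2, GCN=self.GCN / 2,
            GWt=self.GWt / 2, GCt=self.GCt / 2, NSt=self.NSt / 2,
        )


def _nonneg(params: Any, names: tuple[str, ...]) -> None:
    for name in names:
        if getattr(params, name) < 0:
            raise ValueError(f"rate constant {name} must be >= 0")


@dataclass
class ExpressionParams:
    """Rate constants of the transcription-machinery / gene-binding core."""

    kGiTmAs: float = 1000.0   # TM association to size-independent genes (AV/AU/time)
    kGiTmDs: float = 0.1      # ... dissociation (1/time)
    kGdTmAs: float = 100.0    # TM association to size-dependent genes
    kGdTmDs: float = 1.0      # ... dissociation
    kTmSy: float = 1.4        # TM synthesis per active size-dependent gene
    kVoSy: float = 1.4        # volume synthesis per active size-dependent gene
    kPiSy: float = 1.0        # generic size-independent protein synthesis
    kPdSy: float = 1.0        # generic size-dependent protein synthesis
    kPiDe: float = 0.05       # generic protein degradation
    kPdDe: float = 0.05

    def __post_init__(self) -> None:
        _nonneg(self, tuple(f.name for f in fields(ExpressionParams)))
        if min(self.kGiTmAs, self.kGdTmAs, self.kGiTmDs, self.kGdTmDs) > 0:
            if self.kGiTmAs / self.kGiTmDs <= self.kGdTmAs / self.kGdTmDs:
                raise ValueError(
                    "size-independent genes must bind TM more tightly: "
                    "kGiTmAs/kGiTmDs > kGdTmAs/kGdTmDs"
                )


@dataclass
class DilutionParams(ExpressionParams):
    """Full parameter set of the inhibitor-dilution cell-cycle model."""

    # cyclin synthesis / degradation
    kCln3Sy: float = 10.0
    kClnSy: float = 40.0
    kClbSy: float = 0.6
    kClbClbSy: float = 3.0
    jClbSy: float = 0.05
    kCln3De: float = 1.0
    kClnDe: float = 1.0
    kClbDe: float = 0.03
    kClbCdhDe: float = 1.0
    # Whi5 / SBF interaction
    kWhiSbfAs: float = 50.0
    kWhiSbfDs: float = 0.005
    kWhiDp: float = 1.0
    kSbfDp: float = 0.2
    kWhiSy: float = 0.3
    # Whi5 / SBF phosphorylation (concentration based)
    kWhiCln3Ph: float = 5.0
    kWhiClnPh: float = 20.0
    kWhiClbPh: float = 2.0
    kSbfClbPh: float = 5.0
    # APC/C regulation
    kCdhAc: float = 0.05
    kCdhCdcAc: float = 1.0
    kCdhClnIn: float = 1.0
    kCdhClbIn: float = 1.0
    kCdcClbAc: float = 0.2
    kCdcIn: float = 0.02
    jCdh: float = 0.05
    jCdc: float = 0.05
    # event thresholds (concentrations, AU/AV)
    StartThr: float = 0.1
    MitosisThr: float = 0.04

    def __post_init__(self) -> None:
        super().__post_init__()
        _nonneg(self, tuple(
            f.name for f in fields(DilutionParams)
            if f.name not in {x.name for x in fields(ExpressionParams)}
        ))
        for name in ("jClbSy", "jCdh", "jCdc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"Michaelis constant {name} must be > 0")


@dataclass
class TitrationParams(DilutionParams):
    """Parameter set of the titration-of-nuclear-sites model.

    Shared constants (growth, Cln1/2, Clb1/2, APC/C, Whi5 synthesis, SBF
    phosphorylation bookkeeping) reuse the dilution fields.  ``kWhiCln3Ph``
    is re-purposed as the hypo-phosphorylation rate of Whi5 inside the
    Cln3:Whi5:SBF trimer; ``kWhiSbfDs`` and ``kWhiClbPh`` are unused (site
    binding of Whi5 is effectively irreversible and Clb1/2 does not
    phosphorylate free Whi5 in this variant).
    """

    kCln3WhiAs: float = 200.0   # Cln3 binding to Whi5:SBF on sites
    kCln3WhiDs: float = 0.05    # ... dissociation
    kWhipCln3Ph: float = 10.0   # hyper-phosphorylation of Whi5P:SBF by free Cln3
    kWhipClnPh: float = 10.0    # ... by Cln1/2

    def __post_init__(self) -> None:
        super().__post_init__()
        _nonneg(self, ("kCln3WhiAs", "kCln3WhiDs", "kWhipCln3Ph", "kWhipClnPh"))


_VARIANT_CLASSES = {"dilution": DilutionParams, "titration": TitrationParams}
_VARIANT_FILES = {"dilution": "params_dilution.yaml", "titration": "params_titration.yaml"}

# genome keys that may appear in a flat parameter file alongside rate constants
_GENOME_KEYS = tuple(f.name for f in fields(GenomeConfig))


def _split_mapping(mapping: dict[str, Any], cls: type) -> tuple[dict, dict]:
    param_names = {f.name for f in fields(cls)}
    params = {k: float(v) for k, v in mapping.items() if k in param_names}
    genome = {k: float(v) for k, v in mapping.items() if k in _GENOME_KEYS}
    known = param_names | set(_GENOME_KEYS) | {"variant"}
    unknown = set(mapping) - known
    if unknown:
        raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
    return params, genome


def load_params(path: str | Path, variant: str | None = None):
    """Read a flat YAML parameter file.

    Returns ``(params, genome)``.  The model variant is taken from the
    file's ``variant`` key unless overridden.
    """
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise ValueError(f"{path}: expected a flat key-value mapping")
    variant = variant or mapping.get("variant")
    if variant not in _VARIANT_CLASSES:
        raise ValueError(f"unknown model variant {variant!r}")
    cls = _VARIANT_CLASSES[variant]
    params_kw, genome_kw = _split_mapping(mapping, cls)
    return cls(**params_kw), GenomeConfig(**genome_kw)


def save_params(path: str | Path, params, genome: GenomeConfig, variant: str) -> None:
    """Write parameters and genome configuration as flat YAML."""
    mapping: dict[str, Any] = {"variant": variant}
    mapping.update(dataclasses.asdict(params))
    mapping.update(dataclasses.asdict(genome))
    with open(path, "w") as fh:
        yaml.safe_dump(mapping, fh, sort_keys=False)


def default_params(variant: str):
    """Bundled calibrated defaults for a model variant.

    Returns ``(params, genome)`` for a haploid wild-type cell.
    """
    if variant not in _VARIANT_FILES:
        raise ValueError(f"unknown model variant {variant!r}")
    ref = resources.files("sizecycle.data") / _VARIANT_FILES[variant]
    with resources.as_file(ref) as path:
        return load_params(path, variant=variant)


def default_genome(variant: str) -> GenomeConfig:
    return default_params(variant)[1]


def scale_growth(params, f: float):
    """Scale the specific growth rate by a factor ``f``.

    Both ``kVoSy`` and ``kTmSy`` change by the same factor, which changes
    the growth rate while keeping the transcriptional capacity per unit
    volume (TMt/Vt = kTmSy/kVoSy) unchanged.
    """
    if f <= 0:
        raise ValueError("growth-rate factor must be > 0")
    return dataclasses.replace(params, kTmSy=f * params.kTmSy, kVoSy=f * params.kVoSy)
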