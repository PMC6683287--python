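"""Run configuration and stage logging.

All tunable parameters of the workflow live in :class:`RunConfig`; the
defaults are the study's operating point (BBH e-value < 1e-5, >= 3 ORFs
per contig, 95% concordance target, fragment sizes 5-60 genes, lifestyle
switch above 19 proteins).  A YAML file can override any subset.  Every
source of randomness flows from the single ``seed``.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import yaml

from .calibration import DEFAULT_TARGET, FRAGMENT_SIZES
from .classify import DEFAULT_MIN_ORFS, DEFAULT_PRECEDENCE, LIFESTYLE_PROTEIN_MIN
from .diversity import BETA_MODES
from .wgrr import DEFAULT_EVALUE_MAX, InputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    evalue_max: float = DEFAULT_EVALUE_MAX
    min_orfs: int = DEFAULT_MIN_ORFS
    concordance_target: float = DEFAULT_TARGET
    fragment_sizes: tuple[int, ...] = FRAGMENT_SIZES
    n_fragments_per_phage: int = 1
    lifestyle_protein_min: int = LIFESTYLE_PROTEIN_MIN
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE
    use_phage_markers: bool = False
    beta_mode: str = "turnover"
    rarefaction_depth: Optional[int] = None  # None -> min column sum
    seed: int = 42

    def validate(self) -> "RunConfig":
        if self.evalue_max <= 0:
            raise InputError("evalue_max must be positive")
        if self.min_orfs < 1:
            raise InputError("min_orfs must be >= 1")
        if not 0 < self.concordance_target <= 1:
            raise InputError("concordance_target must be in (0, 1]")
        if not self.fragment_sizes or any(s < 1 for s in self.fragment_sizes):
            raise InputError("fragment_sizes must be positive")
        if self.beta_mode not in BETA_MODES:
            raise InputError(f"beta_mode must be one of {BETA_MODES}")
        if set(self.precedence) != set(DEFAULT_PRECEDENCE):
            raise InputError(
                f"precedence must be a permutation of {DEFAULT_PRECEDENCE}"
            )
        return self

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise InputError(f"{path}: config must be a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise InputError(f"{path}: unknown config keys {sorted(unknown)}")
        for key in ("fragment_sizes", "precedence"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data).validate()

    def to_yaml(self, path: Union[str, Path]) -> None:
        data = asdict(self)
        data["fragment_sizes"] = list(self.fragment_sizes)
        data["precedence"] = list(self.precedence)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs).validate()


@dataclass(frozen=True)
class StageRecord:
    stage: str
    n_in: int
    n_kept: int

    @property
    def n_removed(self) -> int:
        return self.n_in - self.n_kept


@dataclass
class RunLog:
    """In/out counts per stage; counts are conserved (in = kept + removed)."""

    records: list[StageRecord] = field(default_factory=list)

    def record(self, stage: str, n_in: int, n_kept: int) -> StageRecord:
        if not 0 <= n_kept <= n_in:
            raise InputError(
                f"stage {stage!r}: kept {n_kept} outside [0, in={n_in}]"
            )
        rec = StageRecord(stage, n_in, n_kept)
        self.records.append(rec)
        logger.info("%s: %d in, %d kept, %d removed", stage, n_in, n_kept,
                    rec.n_removed)
        return rec

    def to_dict(self) -> dict:
        return {
            r.stage: {"in": r.n_in, "kept": r.n_kept, "removed": r.n_removed}
            for r in self.records
        }
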