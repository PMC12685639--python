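"""Run configuration shared by every analysis stage.

A single :class:`RunConfig` travels through the pipeline so that every
output artifact records the seed, bootstrap size and thresholds that
produced it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any


@dataclass
class RunConfig:
    """Analysis-wide settings.

    Parameters
    ----------
    seed : int
        Master seed; every random stream in the pipeline derives from it.
    n_bootstrap : int
        Cluster-bootstrap replicates for mediation intervals.
    alpha : float
        Two-sided significance level used for gating and flags.
    gwsig_threshold : float
        Genome-wide significance p-value threshold for instrument selection.
    palindrome_maf_limit : float
        Minor-allele-frequency ceiling below which a palindromic (A/T or
        C/G) variant is considered orientable during harmonization.
    ivw_model : str
        ``"random"`` (multiplicative random effects, default) or
        ``"fixed"`` inverse-variance weighting.
    rcs_knots : int
        Number of knots in the restricted cubic spline basis.
    """

    seed: int = 0
    n_bootstrap: int = 1000
    alpha: float = 0.05
    gwsig_threshold: float = 5e-8
    palindrome_maf_limit: float = 0.42
    ivw_model: str = "random"
    rcs_knots: int = 4

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int,)):
            raise ValueError("seed must be an integer")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be a positive integer")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.gwsig_threshold < 1.0:
            raise ValueError("gwsig_threshold must lie in (0, 1)")
        if not 0.0 < self.palindrome_maf_limit < 0.5:
            raise ValueError("palindrome_maf_limit must lie in (0, 0.5)")
        if self.ivw_model not in ("fixed", "random"):
            raise ValueError("ivw_model must be 'fixed' or 'random'")
        if self.rcs_knots < 3:
            raise ValueError("rcs_knots must be >= 3")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_file(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        """Load a flat key=value config file; keyword overrides win."""
        values: dict[str, Any] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            val = val.strip()
            if key in ("seed", "n_bootstrap", "rcs_knots"):
                values[key] = int(val)
            elif key in ("alpha", "gwsig_threshold", "palindrome_maf_limit"):
                values[key] = float(val)
            else:
                values[key] = val
        values.update(overrides)
        return cls(**values)


@dataclass
class AnalysisReport:
    """Serializable record of one analysis stage.

    Holds the stage name, the configuration echo, result tables (as
    lists of records) and any warnings raised during the run.  Writing
    then reading a report reproduces its content exactly.
    """

    stage: str
    config: dict[str, Any]
    tables: dict[str, list[dict[str, Any]]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), indent=2, sort_keys=True, default=_jsonify)
            + "\n"
        )

    @classmethod
    def read(cls, path: str | Path) -> "AnalysisReport":
        data = json.loads(Path(path).read_text())
        return cls(**data)


def _jsonify(obj: Any) -> Any:
    try:
        return obj.item()  # numpy scalars
    except AttributeError:
        return str(obj)
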