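"""Run configuration shared by the library pipeline and the CLI."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass
class RunConfig:
    """Parameters of a two-sample (or multi-sample) comparison.

    Defaults follow the method's published defaults: 500 highly variable
    genes, 4 principal components, k = 10 clusters, 1000 permutations,
    alpha = 0.05.  ``scale_factor=None`` means "median library size of the
    pooled cells".  ``no_normalize`` routes continuous inputs (e.g. mass
    cytometry) straight to the embedding.
    """

    hvg_count: int = 500
    n_components: int = 4
    k: int = 10
    n_permutations: int = 1000
    alpha: float = 0.05
    scale_factor: float | None = None
    pseudocount: float = 1.0
    linkage: str = "average"
    seed: int = 0
    no_normalize: bool = False
    conservative_p: bool = False

    def __post_init__(self) -> None:
        for name in ("hvg_count", "n_components", "k", "n_permutations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.scale_factor is not None and self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write_echo(self, path: str | Path) -> None:
        """Write the resolved configuration so a run can be reproduced exactly."""
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})
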