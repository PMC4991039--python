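"""Numeric thresholds of the SNP filter cascade.

Defaults follow the read-alignment and genotype-calling criteria used to
build the high-quality 1:1 SNP set for an outbred F1 family: alignment
records are dropped when the edit distance exceeds 9, the best alignment
score falls below 60, or a second-best alignment outscores the best; SNP
sites are discovered in a parent at mapping quality >= 20 and depth >= 5;
individual genotype calls require DP >= 10 and GQ strictly > 50; markers
are removed when their 1:1 segregation chi-square p-value is below .01 or
more than 10 % of progeny calls are missing.
"""

from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass(frozen=True)
class FilterConfig:
    """All thresholds of the filter cascade, each independently tunable."""

    max_edit_distance: int = 9
    min_best_score: int = 60
    min_site_mq: float = 20.0
    min_discovery_dp: int = 5
    min_genotype_dp: int = 10
    min_gq: int = 50          # strict: calls need GQ > min_gq
    max_missing: float = 0.10  # strict: markers with missing > max_missing removed
    min_segregation_p: float = 0.01

    def __post_init__(self) -> None:
        if self.max_edit_distance < 0:
            raise ValueError("max_edit_distance must be non-negative")
        if not (0.0 <= self.max_missing <= 1.0):
            raise ValueError("max_missing must lie in [0, 1]")
        if not (0.0 <= self.min_segregation_p <= 1.0):
            raise ValueError("min_segregation_p must lie in [0, 1]")

    def replace(self, **kwargs) -> "FilterConfig":
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(kwargs)
        return FilterConfig(**current)
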