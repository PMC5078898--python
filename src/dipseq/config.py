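"""Pipeline configuration: one dataclass holding every tunable threshold.

Defaults encode the analysis conditions used throughout: a 1000 bp sliding
window for enrichment segmentation, DMR calling at q < 0.01 with a
normalized tag difference above 50 in 5 kb testing units, gene annotation
within 50 kb of a TSS (25 kb as the documented alternate), top-2000 DMRs
for ontology work, top-1000 sets for overlap testing, top-500 for the
intragenic-difference ranking, and heatmap color ceilings at the 80 %
quantile.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # segmentation
    window_bp: int = 1000
    window_step_bp: int | None = None  # None -> window_bp // 2 ("sliding")
    n_permutations: int = 500
    enrich_alpha: float = 0.01
    # differential methylation
    dmr_q_threshold: float = 0.01
    dmr_min_tag_diff: float = 50.0
    dmr_window_bp: int = 5000
    dmr_test: str = "chisq"  # "chisq" (pooled counts) or "nb" (replicate-aware)
    dmr_diff_mode: str = "normalized"  # or "raw"
    dmr_unit: str = "tiles"  # re-tile merged territory; "merged" tests whole regions
    # annotation / integration
    tss_max_dist_bp: int = 50_000  # alternate 25_000
    tss_anchor: str = "midpoint"  # or "edge"
    top_n_dmrs: int = 2000
    top_n_overlap: int = 1000
    top_n_intragenic: int = 500
    heatmap_quantile: float = 0.80
    metagene_body_bins: int = 50
    metagene_flank_bp: int = 2000
    metagene_flank_bins: int = 20
    # expression
    expression_q_threshold: float = 0.05
    count_mode: str = "exon"  # or "span"
    # tags
    fragment_extension_bp: int = 0
    collapse_duplicates: bool = False
    # enrichment
    enrichment_q_threshold: float = 0.01
    # reproducibility
    rng_seed: int = 0

    def __post_init__(self):
        self.validate()

    @property
    def step_bp(self) -> int:
        return self.window_step_bp if self.window_step_bp else max(1, self.window_bp // 2)

    def validate(self) -> None:
        positive = {
            "window_bp": self.window_bp,
            "n_permutations": self.n_permutations,
            "enrich_alpha": self.enrich_alpha,
            "dmr_q_threshold": self.dmr_q_threshold,
            "dmr_min_tag_diff": self.dmr_min_tag_diff,
            "dmr_window_bp": self.dmr_window_bp,
            "tss_max_dist_bp": self.tss_max_dist_bp,
            "top_n_dmrs": self.top_n_dmrs,
            "top_n_overlap": self.top_n_overlap,
            "top_n_intragenic": self.top_n_intragenic,
            "metagene_body_bins": self.metagene_body_bins,
            "metagene_flank_bins": self.metagene_flank_bins,
            "expression_q_threshold": self.expression_q_threshold,
            "enrichment_q_threshold": self.enrichment_q_threshold,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"config field {name} must be positive, got {value}")
        if self.window_step_bp is not None and not (
            1 <= self.window_step_bp <= self.window_bp
        ):
            raise ValueError("window_step_bp must lie in [1, window_bp]")
        if not (0.0 < self.heatmap_quantile < 1.0):
            raise ValueError(
                f"heatmap_quantile must lie in (0, 1), got {self.heatmap_quantile}"
            )
        if self.dmr_test not in ("chisq", "nb"):
            raise ValueError("dmr_test must be 'chisq' or 'nb'")
        if self.dmr_diff_mode not in ("normalized", "raw"):
            raise ValueError("dmr_diff_mode must be 'normalized' or 'raw'")
        if self.dmr_unit not in ("tiles", "merged"):
            raise ValueError("dmr_unit must be 'tiles' or 'merged'")
        if self.count_mode not in ("exon", "span"):
            raise ValueError("count_mode must be 'exon' or 'span'")
        if self.tss_anchor not in ("midpoint", "edge"):
            raise ValueError("tss_anchor must be 'midpoint' or 'edge'")
        if self.fragment_extension_bp < 0:
            raise ValueError("fragment_extension_bp must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
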