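"""Threshold configuration shared by all pipeline stages.

Every cutoff used anywhere in the pipeline lives in :class:`ThresholdConfig`
so that a single YAML file can drive a full run and alternative published
threshold sets (e.g. looser unmethylated cutoffs) can be expressed without
code changes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

#: The six methylation-domain labels, in classification (hierarchy) order.
DOMAIN_LABELS = (
    "missing_data",
    "rddm",
    "heterochromatin",
    "cg_only",
    "unmethylated",
    "intermediate",
)

#: Domain labels counted as "methylated" in cross-genotype comparisons.
METHYLATED_LABELS = frozenset({"rddm", "heterochromatin", "cg_only"})

#: Cytosine sequence contexts.
CONTEXTS = ("CG", "CHG", "CHH")

#: Bin-mapping statuses that count as shared space.
SHARED_STATUSES = frozenset({"shared_exact", "shared_snp", "shared_indel"})


@dataclass
class ThresholdConfig:
    """All tunable thresholds of the pipeline (units noted per field)."""

    # --- methylation-domain classification (levels are fractions in [0,1]) ---
    chh_rddm: float = 0.15          # CHH level strictly above -> RdDM
    cg_chg_het: float = 0.40        # CG and CHG both >= -> heterochromatin
    cg_only: float = 0.40           # CG strictly above -> CG-only
    unmethylated_max: float = 0.10  # all contexts strictly below -> unmethylated
    intermediate_low: float = 0.10
    intermediate_high: float = 0.40
    min_sites: int = 2              # cytosines per bin, pooled over contexts
    min_coverage: float = 5.0       # reads per site, pooled over contexts

    # --- UMR calling ---
    bin_size: int = 100             # bp
    umr_min_len: int = 300          # bp; shorter UMRs removed
    umr_max_missing: float = 1.0 / 3.0  # missing-bin fraction must stay below
    proximal_bp: int = 2000         # gene-proximal distance cutoff (inclusive)

    # --- ACR post-processing ---
    acr_window: int = 50            # bp
    acr_step: int = 25              # bp
    acr_fold: float = 25.0          # normalized Tn5 frequency strictly above
    acr_max_gap: int = 150          # bp between qualifying windows
    acr_min_len: int = 50           # bp; regions must be strictly longer

    # --- cross-genotype bin mapping ---
    max_indels: int = 4             # indel events per bin allowed in shared space
    max_indel_len: int = 20         # bp per indel event

    # --- IBS detection ---
    ibs_window: int = 1_000_000     # bp
    ibs_max_density: float = 0.0005  # SNPs per syntenic bp, strictly below
    ibs_min_span: int = 5_000_000   # bp

    # --- DMT calling ---
    dmt_diff: float = 0.40          # |level_A - level_B| >= (CG/CHG)
    dmt_low: float = 0.10           # min level strictly below (CG/CHG)
    dmt_high: float = 0.40          # max level strictly above (CG/CHG)
    dmt_chh_low: float = 0.05       # min level strictly below (CHH)
    dmt_chh_high: float = 0.25      # max level strictly above (CHH)

    # --- comparative classification ---
    polymorphic_min_frac: float = 0.5   # methylated target-bin fraction strictly above
    missing_target_max: float = 0.5     # no-data target-bin fraction strictly above -> missing
    tss_window: int = 200               # bp around the TSS for expression linkage
    de_lfc: float = 2.0                 # |log2FC| strictly above -> DE
    de_p: float = 0.05                  # p-value strictly below -> DE
    expr_floor: float = 1.0             # mean expression below in both -> silent

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.intermediate_low < self.intermediate_high:
            raise ValueError("intermediate_low must be < intermediate_high")
        if self.unmethylated_max > self.intermediate_low:
            raise ValueError("unmethylated_max must be <= intermediate_low")
        if self.min_sites < 0 or self.min_coverage < 0:
            raise ValueError("min_sites and min_coverage must be non-negative")
        if not 0 < self.umr_max_missing <= 1:
            raise ValueError("umr_max_missing must be in (0, 1]")

    # -- serialisation ------------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Stable short hash identifying this threshold set."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
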