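"""Analysis configuration.

All statistical knobs of the pipeline live in one dataclass so a run is
fully described by (input files, :class:`AnalysisConfig`, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml


@dataclass
class AnalysisConfig:
    """Parameters of the differential-expression / validation pipeline.

    Attributes
    ----------
    alpha_fdr:
        FDR (Benjamini-Hochberg) significance level for calling a gene
        differentially expressed in a pairwise contrast.
    strategy1_pool_size:
        Size of each of the two high-expression pools (one ranked by mean
        expression in sepsis, one in SIRS) joined by selection strategy 1.
    strategy1_top_k:
        Number of smallest-q genes taken from the joined pool in
        strategy 1 before range-rule additions.
    strategy2_fc_high:
        Minimum linear fold change sepsis vs. SIRS for strategy 2.
    strategy2_fc_low:
        Maximum linear fold change SIRS vs. presurgical for strategy 2.
    confirm_min_n:
        Minimum number of above-background samples per group for a
        bead-array signal to count as "expression confirmed" in that group.
    alpha_validation:
        Significance level applied to Bonferroni-adjusted Mann-Whitney
        p-values in the validation step.
    n_permutations:
        Number of permutations for the enrichment null distribution.
    min_set_size:
        Gene sets whose intersection with the ranked universe is smaller
        than this are skipped by the enrichment step.
    seed:
        Seed for every stochastic step (enrichment permutations).
    exclusion_list:
        Genes removed from strategy 1's top-k list without replacement
        (e.g. genes for which no validation assay could be designed).
    """

    alpha_fdr: float = 0.05
    strategy1_pool_size: int = 100
    strategy1_top_k: int = 50
    strategy2_fc_high: float = 2.0
    strategy2_fc_low: float = 1.1
    confirm_min_n: int = 4
    alpha_validation: float = 0.05
    n_permutations: int = 200
    min_set_size: int = 5
    seed: int = 0
    exclusion_list: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for name in ("alpha_fdr", "alpha_validation"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {a!r}")
        for name in (
            "strategy1_pool_size",
            "strategy1_top_k",
            "strategy2_fc_high",
            "strategy2_fc_low",
            "confirm_min_n",
            "n_permutations",
            "min_set_size",
        ):
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v!r}")
        self.exclusion_list = tuple(self.exclusion_list)


def load_config(path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from a YAML mapping.

    Unknown keys raise, so typos in a config file fail loudly.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {f.name for f in fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**raw)
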