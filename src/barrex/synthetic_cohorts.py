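"""Multi-cohort synthetic expression data with known ground truth.

The generator emulates the structure the meta-analysis assumes: several
cohorts profiled on distinct array platforms whose gene panels overlap but do
not coincide; three tissue groups (squamous S, Barrett's esophagus BE,
adenocarcinoma EAC) per cohort; planted fold-change signatures for chosen
genes in the S->BE and/or BE->EAC comparison; heteroscedastic per-gene,
per-group noise (which is what makes Welch's test the right one); a small
fraction of samples that are mixtures of two tissue profiles (emulating
biopsy tissue heterogeneity, the explanation offered for dendrogram
misclassifications); and probe-annotation defects (multi-mapped and unmapped
probes) at configurable rates.

Expression values are generated log2-normally — per-gene, per-group log2
values are Normal(mu, sd) — and exported on the linear scale (2**x) so the
preprocessing chain is exercised end to end.  A planted fold ratio r is
defined on linear-scale arithmetic group means, the quantity the downstream
fold-change statistic measures: because E[2^X] = 2^(mu + ln2/2 * sd^2) under
log2-normal noise, the planted log2 offset is log2(r) minus the lognormal
correction term (ln2/2)(sd_b^2 - sd_a^2), making the expected arithmetic-mean
ratio exactly r even with unequal group variances.  Background genes have
identical log2 group means, so the significance machinery sees a true null.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from math import log
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .expression_io import CohortExpression, TISSUES, write_json

Comparison = Literal["S_BE", "BE_EAC"]

_LN2 = log(2.0)


@dataclass(frozen=True)
class Signature:
    """One planted differential-expression signal.

    ``fold`` is the target ratio of arithmetic group means (BE/S for the
    S->BE comparison, EAC/BE for BE->EAC); values below 1 plant a decrease.
    """

    gene: int
    comparison: Comparison
    fold: float

    def __post_init__(self) -> None:
        if not self.fold > 0:
            raise ValueError(f"fold ratio must be > 0, got {self.fold}")
        if self.comparison not in ("S_BE", "BE_EAC"):
            raise ValueError(f"unknown comparison {self.comparison!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic multi-cohort experiment.

    Defaults mirror the real four-cohort design: four platforms, three tissue
    groups per cohort with group sizes near the per-cohort averages of the
    combined 72 squamous / 81 BE / 78 EAC samples, platforms covering
    overlapping but unequal gene panels, and a small mixed-tissue fraction.
    The master gene count is a scaled-down universe (thousands rather than
    tens of thousands) so simulated runs stay fast; rates and noise levels
    are per-gene realistic for log2 array intensities.
    """

    n_cohorts: int = 4
    group_sizes: tuple[int, int, int] = (18, 20, 20)  # (S, BE, EAC) per cohort
    master_gene_count: int = 2000
    platform_overlap: float = 0.8
    signatures: tuple[Signature, ...] = ()
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    noise_sd_range: tuple[float, float] = (0.3, 0.8)
    contamination_rate: float = 0.05
    contamination_weight: float = 0.5
    multimap_rate: float = 0.02
    unmapped_rate: float = 0.05
    ensure_recoverable: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cohorts < 1 or self.master_gene_count < 1:
            raise ValueError("counts must be >= 1")
        if any(g < 1 for g in self.group_sizes):
            raise ValueError("group sizes must be >= 1")
        for name in ("platform_overlap", "contamination_rate",
                     "contamination_weight", "multimap_rate", "unmapped_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.noise_sd_range
        if not (0 < lo <= hi):
            raise ValueError("noise_sd_range must satisfy 0 < low <= high")
        genes = set(range(1, self.master_gene_count + 1))
        for sig in self.signatures:
            if sig.gene not in genes:
                raise ValueError(
                    f"signature gene {sig.gene} is not in the master universe "
                    f"(1..{self.master_gene_count})")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset."""

    signatures: list[Signature]
    platform_presence: dict[int, list[str]]   # gene -> cohorts carrying it
    mapped_presence: dict[int, list[str]]     # after annotation defects
    contaminated: list[dict]                  # cohort, sample, source, weight
    probe_defects: dict[str, dict[str, list[str]]]

    def signature_genes(self, comparison: Comparison | None = None) -> set[int]:
        return {s.gene for s in self.signatures
                if comparison is None or s.comparison == comparison}

    def to_json(self, path) -> None:
        payload = {
            "signatures": [asdict(s) for s in self.signatures],
            "platform_presence": {str(g): c for g, c in self.platform_presence.items()},
            "mapped_presence": {str(g): c for g, c in self.mapped_presence.items()},
            "contaminated": self.contaminated,
            "probe_defects": self.probe_defects,
        }
        write_json(payload, path)


def _assign_panels(config: SimulationConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Choose each cohort's gene panel (without replacement per cohort)."""
    genes = np.arange(1, config.master_gene_count + 1)
    panel_size = max(1, round(config.platform_overlap * config.master_gene_count))
    panels = [set(rng.choice(genes, size=panel_size, replace=False))
              for _ in range(config.n_cohorts)]
    if config.ensure_recoverable and config.n_cohorts >= 3:
        for sig in config.signatures:
            carriers = [i for i, p in enumerate(panels) if sig.gene in p]
            missing = 3 - len(carriers)
            if missing > 0:
                others = [i for i in range(config.n_cohorts) if i not in carriers]
                for i in rng.choice(others, size=missing, replace=False):
                    panels[int(i)].add(sig.gene)
    return [np.array(sorted(p)) for p in panels]


def generate_cohorts(config: SimulationConfig
                     ) -> tuple[list[CohortExpression], SyntheticTruth]:
    """Generate the configured cohorts plus their ground truth.

    Outputs are deterministic in (config, seed): the same configuration gives
    byte-identical matrices, annotations and truth.
    """
    rng = np.random.default_rng(config.seed)
    panels = _assign_panels(config, rng)
    sig_by_gene: dict[int, list[Signature]] = {}
    for sig in config.signatures:
        sig_by_gene.setdefault(sig.gene, []).append(sig)

    cohorts: list[CohortExpression] = []
    truth = SyntheticTruth(
        signatures=list(config.signatures),
        platform_presence={}, mapped_presence={}, contaminated=[],
        probe_defects={},
    )
    n_s, n_be, n_eac = config.group_sizes
    group_of = np.array(
        ["S"] * n_s + ["BE"] * n_be + ["EAC"] * n_eac)

    for ci in range(config.n_cohorts):
        name = f"C{ci + 1}"
        panel = panels[ci]
        G = panel.size
        for g in panel:
            truth.platform_presence.setdefault(int(g), []).append(name)

        base = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=G)
        sd = rng.uniform(*config.noise_sd_range, size=(G, 3))  # per gene x group

        # log2 group means: background genes share the baseline; planted genes
        # get log2(fold) minus the lognormal mean-correction so the *linear
        # arithmetic* mean ratio equals the planted fold exactly.
        mu = np.tile(base[:, None], (1, 3))
        gene_pos = {int(g): i for i, g in enumerate(panel)}
        for gene, sigs in sig_by_gene.items():
            i = gene_pos.get(gene)
            if i is None:
                continue
            for sig in sigs:
                a, b = (0, 1) if sig.comparison == "S_BE" else (1, 2)
                delta = np.log2(sig.fold) - (_LN2 / 2.0) * (sd[i, b] ** 2 - sd[i, a] ** 2)
                mu[i, b:] += delta  # shift carries through later tissue states

        samples = [f"{name}_{t}{j + 1}"
                   for t in ("s", "b", "e")
                   for j in range(config.group_sizes[("s", "b", "e").index(t)])]
        n_total = len(samples)
        gidx = np.array([TISSUES.index(t) for t in group_of])

        log2 = mu[:, gidx] + rng.normal(size=(G, n_total)) * sd[:, gidx]

        contaminated = rng.random(n_total) < config.contamination_rate
        for si in np.flatnonzero(contaminated):
            own = gidx[si]
            other = int(rng.choice([g for g in range(3) if g != own]))
            w = config.contamination_weight
            mix_linear = ((1 - w) * np.power(2.0, mu[:, own])
                          + w * np.power(2.0, mu[:, other]))
            log2[:, si] = np.log2(mix_linear) + rng.normal(size=G) * sd[:, own]
            truth.contaminated.append({
                "cohort": name, "sample": samples[si],
                "tissue": TISSUES[own], "mixed_with": TISSUES[other],
                "weight": w,
            })

        probes = np.array([f"{name}_p{int(g)}" for g in panel])
        matrix = pd.DataFrame(np.power(2.0, log2), index=probes, columns=samples)
        labels = pd.Series(group_of, index=samples, name="tissue")

        # annotation defects corrupt annotation rows, never expression values
        protected = (np.isin(panel, list(sig_by_gene))
                     if config.ensure_recoverable else np.zeros(G, bool))
        u = rng.random(G)
        unmapped = (u < config.unmapped_rate) & ~protected
        multimap = ((u >= config.unmapped_rate)
                    & (u < config.unmapped_rate + config.multimap_rate)
                    & ~protected)
        status = np.where(unmapped, "unmapped",
                          np.where(multimap, "multimapped", "ok"))
        annotation = pd.DataFrame({
            "entrez": pd.array([pd.NA if s != "ok" else int(g)
                                for g, s in zip(panel, status)], dtype="Int64"),
            "symbol": [f"G{int(g)}" for g in panel],
            "status": status,
        }, index=probes)
        annotation.index.name = "probe_id"
        truth.probe_defects[name] = {
            "unmapped": list(probes[unmapped]),
            "multimapped": list(probes[multimap]),
        }
        for g, s in zip(panel, status):
            if s == "ok":
                truth.mapped_presence.setdefault(int(g), []).append(name)

        cohorts.append(CohortExpression(
            name=name, matrix=matrix, labels=labels,
            annotation=annotation, scale="linear",
        ))
    return cohorts, truth


def plant_signatures(genes: Sequence[int], comparison: Comparison,
                     fold: float) -> tuple[Signature, ...]:
    """Convenience: one identical signature per gene."""
    return tuple(Signature(gene=int(g), comparison=comparison, fold=fold)
                 for g in genes)
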