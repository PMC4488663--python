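"""Type-I-error, power and benchmark-enrichment evaluation on synthetic data.

The protocol mirrors a standard gene-set tool evaluation: replicate
datasets are generated under the null (phenotype independent of genotype)
to measure the fraction of sets reaching a nominal p-value threshold, and
under planted causal effects to count sets surviving
Benjamini-Hochberg FDR correction.  Relative power against a benchmark
collection is summarized with an upper-tail hypergeometric test.

Problem sizes here are deliberately desk-scale (hundreds of permutations,
tens of replicate datasets); the statistics they estimate are the same as
at full scale, with wider Monte-Carlo error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import annotation as annot
from . import selfcontained, simulate
from .datatypes import GeneSetCollection, PanelSpec, TraitSpec

logger = logging.getLogger(__name__)


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrichment(n_detected_total: int, n_detected_benchmark: int,
                         n_total: int, n_benchmark: int) -> float:
    """Upper-tail hypergeometric p for the benchmark hit count.

    Probability of >= ``n_detected_benchmark`` benchmark sets among
    ``n_detected_total`` draws from ``n_total`` sets of which
    ``n_benchmark`` are benchmark.
    """
    if not (0 <= n_detected_benchmark <= n_detected_total <= n_total):
        raise ValueError("inconsistent counts: need 0 <= k <= n <= N")
    if not (0 <= n_benchmark <= n_total) or n_detected_benchmark > n_benchmark:
        raise ValueError("inconsistent benchmark counts")
    return float(stats.hypergeom.sf(n_detected_benchmark - 1, n_total,
                                    n_benchmark, n_detected_total))


@dataclass
class EvalScenario:
    """A reusable simulation scenario: panel, annotation and gene-sets."""

    panel: PanelSpec
    n_genes: int = 100
    snps_per_gene_range: tuple = (2, 8)
    intergenic_fraction: float = 0.0
    n_sets: int = 100
    genes_per_set: int = 10
    causal_snps: tuple = ()
    flank_bp: int = 0
    _cache: dict = field(default_factory=dict, repr=False)

    def resolved_sets(self):
        """Gene locations, collection and resolved SNP lists (cached).

        SNP identities depend only on the panel's dimensions, so the same
        annotation serves every replicate drawn from this scenario.
        """
        if "sets" not in self._cache:
            data = simulate.simulate_genotypes(self.panel)
            genes, collection = simulate.make_annotation(
                data, self.n_genes, self.snps_per_gene_range, self.intergenic_fraction,
                n_sets=self.n_sets, genes_per_set=self.genes_per_set,
                causal_snps=self.causal_snps, rng_seed=self.panel.rng_seed,
            )
            gene_map = annot.map_snps_to_genes(data.snps, genes,
                                               self.flank_bp, self.flank_bp)
            resolved = annot.resolve_collection(collection, gene_map)
            self._cache.update(genes=genes, collection=collection, sets=resolved)
        return self._cache["genes"], self._cache["collection"], self._cache["sets"]


def type1_error_run(
    scenario: EvalScenario,
    n_datasets: int = 20,
    nperms: int = 500,
    alpha: float = 0.05,
    rng_seed: int = 0,
    binary: bool = False,
) -> float:
    """Mean fraction of sets with self-contained p < alpha under the null.

    Each replicate regenerates genotypes and draws a fresh phenotype with
    no causal SNPs; the average over replicates estimates the type-I error
    rate at level ``alpha``.
    """
    rng = np.random.default_rng(rng_seed)
    _, _, sets = scenario.resolved_sets()
    rates = []
    for _ in range(n_datasets):
        panel = PanelSpec(**{**scenario.panel.__dict__,
                             "rng_seed": int(rng.integers(2**31))})
        data = simulate.simulate_genotypes(panel)
        if binary:
            phen = simulate.simulate_phenotype(
                data, TraitSpec(kind="binary", prevalence=0.5),
                rng_seed=int(rng.integers(2**31)))
        else:
            phen = simulate.simulate_phenotype(
                data, TraitSpec(kind="quantitative"), rng_seed=int(rng.integers(2**31)))
        data = simulate.with_phenotype(data, phen, binary=binary)
        results = selfcontained.run_selfcontained(
            data, sets, nperms, rng_seed=int(rng.integers(2**31)))
        pvals = np.array([r.p_self for r, _ in results if r.p_self is not None])
        rates.append(float((pvals < alpha).mean()))
    rate = float(np.mean(rates))
    logger.info("type-I error at alpha=%g over %d datasets: %.4f", alpha, n_datasets, rate)
    return rate


def power_run(
    scenario: EvalScenario,
    trait: TraitSpec,
    n_datasets: int = 20,
    nperms: int = 500,
    alpha_fdr: float = 0.05,
    rng_seed: int = 0,
) -> dict:
    """Detection counts at BH-FDR < alpha among all and among causal sets.

    The scenario must designate a causal set (``causal_snps`` non-empty, so
    the collection contains SET_CAUSAL).  Returns per-replicate counts and
    their means.
    """
    rng = np.random.default_rng(rng_seed)
    _, collection, sets = scenario.resolved_sets()
    causal_names = {n for n in collection.sets if n == "SET_CAUSAL"}
    if not causal_names:
        raise ValueError("scenario has no causal set; provide causal_snps")

    n_sig, n_causal = [], []
    for _ in range(n_datasets):
        panel = PanelSpec(**{**scenario.panel.__dict__,
                             "rng_seed": int(rng.integers(2**31))})
        data = simulate.simulate_genotypes(panel)
        phen = simulate.simulate_phenotype(data, trait, rng_seed=int(rng.integers(2**31)))
        data = simulate.with_phenotype(data, phen, binary=trait.kind == "binary")
        results = selfcontained.run_selfcontained(
            data, sets, nperms, rng_seed=int(rng.integers(2**31)))
        names = [r.set_name for r, _ in results if r.p_self is not None]
        pvals = np.array([r.p_self for r, _ in results if r.p_self is not None])
        adj = fdr_adjust(pvals)
        sig = {n for n, a in zip(names, adj) if a < alpha_fdr}
        n_sig.append(len(sig))
        n_causal.append(len(sig & causal_names))
    return {
        "n_significant": n_sig,
        "n_causal_detected": n_causal,
        "mean_significant": float(np.mean(n_sig)),
        "causal_detection_rate": float(np.mean([c > 0 for c in n_causal])),
        "n_datasets": n_datasets,
    }


# ---------------------------------------------------------------------------
# scenario config files (key = value text)

_PANEL_KEYS = {"n_samples": int, "n_blocks": int, "snps_per_block": int,
               "within_block_r": float, "missing_rate": float, "rng_seed": int}
_TRAIT_KEYS = {"kind": str, "variance_explained_per_snp": float,
               "odds_ratio": float, "prevalence": float, "binary_mode": str}


def read_scenario(path) -> tuple[PanelSpec, TraitSpec]:
    """Parse a key = value scenario file into panel and trait specs.

    Recognized keys: the PanelSpec fields (plus ``maf_low``/``maf_high``)
    and the TraitSpec fields (plus comma-separated ``causal_snps``).
    """
    panel_kw: dict = {}
    trait_kw: dict = {}
    maf = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, val = (t.strip() for t in line.split("=", 1))
            if key in _PANEL_KEYS:
                panel_kw[key] = _PANEL_KEYS[key](val)
            elif key in _TRAIT_KEYS:
                trait_kw[key] = _TRAIT_KEYS[key](val)
            elif key in ("maf_low", "maf_high"):
                maf[key] = float(val)
            elif key == "causal_snps":
                trait_kw["causal_snps"] = tuple(t for t in val.replace(",", " ").split() if t)
            else:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
    if maf:
        panel_kw["maf_range"] = (maf.get("maf_low", 0.1), maf.get("maf_high", 0.5))
    return PanelSpec(**panel_kw), TraitSpec(**trait_kw)
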