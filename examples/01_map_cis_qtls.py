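"""Map cis-QTLs on a small simulated panel, end to end.

Simulates 150 samples x 40 variants with one planted eQTL among 10
phenotypes, writes VCF/BED files, runs the mapping pipeline with the
beta-approximated permutation scheme, and prints the results table.
"""

import tempfile
from pathlib import Path

from cisqtl import SimConfig, simulate_genotypes, simulate_phenotypes, write_fixture
from cisqtl.cli import RunConfig, read_results, run

workdir = Path(tempfile.mkdtemp())
cfg = SimConfig(
    n_samples=150, n_variants=40, n_phenotypes=10,
    maf_range=(0.2, 0.5), effects={2: (20, 0.8)}, seed=42,
)
g = simulate_genotypes(cfg)
p = simulate_phenotypes(g, cfg)
paths = write_fixture(g, p, None, workdir)

out = workdir / "results.txt"
run(RunConfig(
    vcf=str(paths["vcf"]), bed=str(paths["bed"]), out=str(out),
    scheme="beta", R=1000, seed=1, window=1_000_000,
))

df = read_results(out)
print(df.to_string(index=False, float_format=lambda x: f"{x:.4g}"))
print()
best = df.loc[df["beta_perm_p"].idxmin()]
print(
    f"Planted eQTL: pheno3 <- var21. Top hit: {best.phenotype_id} <- "
    f"{best.best_variant_id}, beta-adjusted P = {best.beta_perm_p:.3g}."
)
print(
    "Each row gives the best variant in the +/-1 Mb window, its nominal "
    "P and slope, and adjusted P-values correcting for all correlated "
    "variants tested (direct empirical and beta-approximated)."
)
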