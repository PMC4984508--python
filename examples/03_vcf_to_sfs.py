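"""RAD VCF -> filtered SNPs -> projected joint minor-allele SFS.

Simulates RAD genotypes under the fitted colonization model, writes them
as a VCF, reads them back, applies the RAD filters (HWE exact test,
<= 3 SNPs per tag, one SNP per tag) and builds the folded joint SFS.
"""

import tempfile
from pathlib import Path

from craterdemog import (
    CRATER_MLE,
    build_joint_minor_sfs,
    crater_colonization_model,
    filter_rad_snps,
    gen_rad_vcf,
    project_sfs,
)
from craterdemog.io import read_vcf_genotypes

model = crater_colonization_model(**CRATER_MLE, samples=(20, 20))
with tempfile.TemporaryDirectory() as d:
    vcf = Path(d) / "rad.vcf"
    table, true_sfs = gen_rad_vcf(
        model, n_sites=60_000, mu=5e-8, missing_rate=0.05, seed=3, path=vcf
    )
    pops = dict(zip(table.individuals, table.populations))
    back = read_vcf_genotypes(vcf, populations=pops)

filtered, report = filter_rad_snps(back, hwe_alpha=0.05, max_snps_per_tag=3)
print("filter report:", report.as_dict())

sfs = build_joint_minor_sfs(filtered, effective_length=60_000.0, n1=18, n2=18)
sfs = project_sfs(sfs, 16, 16)
print(f"projected joint SFS: {sfs.counts.shape}, "
      f"{sfs.n_polymorphic:.1f} polymorphic sites")
print("  -> fractional counts: hypergeometric projection doubles as the")
print("     missing-data policy, downsampling each site's called copies")
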