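"""Absolute quantification of human DNA in stool by droplet digital PCR.

Droplet partitioning is Poisson: lambda = -ln(fraction of negative
droplets). Each detected copy of a single-copy human locus is one genome
equivalent (3.3 pg), and dividing by the 5 ng assay input gives the human
percentage of fecal DNA.
"""

from fecalsig.ddpcr import DropletCounts, quantify
from fecalsig.synthio import simulate_ddpcr

# one detected copy = one genome equivalent
q1 = quantify(DropletCounts(20_000, 1, 19_999))
print(f"~1 positive droplet -> {q1.copies:.2f} copies, {q1.mass_pg:.2f} pg human DNA")

# an inflamed sample: 150 template copies ~ 10% human DNA on a 5 ng input
d = simulate_ddpcr(true_copies=150, n_droplets=20_000, seed=4)
q = quantify(d)
print(
    f"droplets +{d.positive}/-{d.negative}: lambda={q.lambda_per_droplet:.6f}, "
    f"{q.copies:.0f} copies, {q.mass_pg:.0f} pg, human {q.human_pct:.2f}%"
)
# 1515 copies x 3.3 pg would equal the whole 5 ng input (100%); at 150
# copies the Poisson correction recovers the true load within a few
# percent, read out as ~10% human DNA.
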