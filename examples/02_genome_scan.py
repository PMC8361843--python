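"""Discover expanded repeat loci without any annotation (genome scan).

The scan extracts large insertions from the alignments (CIGAR I
operations and split-alignment pairs), keeps insertions that are at
least 70% a single tandem repeat, merges them across reads, and anchors
each cluster to the repeat tract in the reference neighborhood.
"""

import tempfile

from trscout import Parameters, genome_scan
from trscout.simulate import SimParams, make_experiment
from trscout.trfind import motifs_match

LOCI = [
    ("chr4", "HTT", "CAG", 57),
    ("chr9", "FXN", "GAA", 18),
    ("chrX", "FMR1", "CGG", 60),
]

with tempfile.TemporaryDirectory() as tmp:
    bundle = make_experiment(
        "het17", tmp, seed=13,
        sim=SimParams(flank_len=6000, depth=24, read_len_median=4000),
        allele_size=500, loci_spec=LOCI,
    )
    sample = bundle.samples[0]
    params = Parameters()
    loci = genome_scan(sample.alignments(params), bundle.reference, (), params)

    truth = {l.chrom: l for l in bundle.loci}
    print(f"scan found {len(loci)} candidate expansion loci "
          f"(planted: {len(bundle.loci)})\n")
    for locus in loci:
        t = truth[locus.chrom]
        concordant = motifs_match(locus.motifs[0], t.motifs[0], params)
        print(f"{locus.chrom}:{locus.start}-{locus.end}  "
              f"motif {locus.motifs[0]:<14} support {locus.support_events:2d} "
              f"reads  planted motif {t.motifs[0]:<14} "
              f"{'concordant' if concordant else 'DISCORDANT'}")

print("\nEvery planted expansion is rediscovered with a motif equivalent "
      "to the planted one (up to rotation/strand) and an interval "
      "matching the reference tract — no repeat annotation was given.")
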