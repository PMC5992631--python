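"""The supergene concatenation-bias experiment.

Five taxa ((X,(A,(B,C))),O) with a pulse from the distant donor X into A
(gamma = 0.3).  Loci are randomly binned into supergenes of size k; the
per-bin trees vote in a quartet assembly.  At k = 1 the majority of loci
(non-introgressed) win and A sits with (B, C); as k grows, mixed bins are
dragged toward X by the introgressed loci's stronger per-locus signal and
the recovered topology flips.
"""

import radintro as ri

df = ri.fig5_experiment(
    gamma=0.3, n_loci=1500, k_grid=(1, 5, 10, 20, 50, 100), seeds=(0, 1, 2)
)
print(df[["seed", "k", "topology", "support"]].to_string(index=False))
row = df.iloc[0]
print(
    f"\nmean mutations supporting the A+X grouping per locus: "
    f"{row['mean_mut_introgressed_loci']:.1f} in introgressed loci vs "
    f"{row['mean_mut_nonintrogressed_loci']:.1f} in the rest"
)
control = ri.fig5_experiment(gamma=0.0, n_loci=600, k_grid=(1, 20, 100), seeds=(0,))
print("\ngamma = 0 control:", dict(zip(control["k"], control["topology"])))
# 'species' means A recovered with (B,C); 'introgressed' means A pulled to
# the donor X.  The control shows the flip is caused by introgression, not
# by binning itself.
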