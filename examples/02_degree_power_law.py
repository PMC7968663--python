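"""Fit power-law exponents to the in/out degree distributions.

Drug out-degree ("how many targets does a drug hit") and target in-degree
("how many drugs hit a target") are both heavy-tailed; the exponent gamma
of P(k) = A k^-gamma summarizes how dominant the hubs are (smaller gamma =
heavier tail).  Both the log-log least-squares fit and the discrete
maximum-likelihood cross-check are shown.
"""

from dtnet import (
    build_network,
    degrees,
    empirical_distribution,
    fit_power_law,
    generate,
    mean_degree,
    paper_scale_preset,
)

net = build_network(generate(paper_scale_preset(seed=1)))
deg = degrees(net)

print(f"mean degree: {mean_degree(net):.2f} neighbors per node")
for which in ("in", "out"):
    dist = empirical_distribution(deg, which)
    ls = fit_power_law(dist, method="loglog_ls")
    mle = fit_power_law(dist, method="mle")
    print(f"gamma_{which}: least-squares {ls.gamma:.2f} "
          f"(r^2 {ls.r_squared:.2f}), MLE cross-check {mle.gamma:.2f}")

# gamma < 2 indicates an extremely heavy tail: the biggest hubs touch a
# macroscopic fraction of the network.
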