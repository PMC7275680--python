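"""Bundled example data: a 16-plot *Carex nigra* alpine-fen survey.

Per-plot elevation (m a.s.l.), soil phosphorus and potassium (mg/kg), total
and flowering shoot counts, and the published clonal-diversity and
genetic-variation indices of the sedge in each plot (clone number G, clonal
diversity R, mean allele number Na, effective allele number Ne, observed and
unbiased expected heterozygosity Ho/He, fixation index F).  The raw
microsatellite scores behind these indices are not redistributed here; the
table is sufficient to exercise the regression stage and the reporting
layer, and it is what the worked example in the README runs on.
"""

from __future__ import annotations

from .io_formats import PlotEnvironment
from .popgen_stats import PlotDiversity

# plot, elevation, P, K, Ss, Sf, G, R, Na, Ne, Ho, He, F
_FEN_ROWS = [
    ("01", 2299.6, 11.4,  756.8, 565, 35, 2, 0.05, 2.20, 1.20, 0.05, 0.14, 0.69),
    ("02", 2299.9, 16.6,  769.1, 815, 39, 1, 0.00, 1.80, 1.29, 0.00, 0.13, 1.00),
    ("03", 2299.4,  5.8,  690.6, 730, 31, 3, 0.11, 2.20, 1.50, 0.18, 0.29, 0.55),
    ("04", 2299.8, 15.3, 1007.2, 850, 55, 3, 0.11, 1.80, 1.45, 0.11, 0.26, 0.54),
    ("05", 2299.7, 16.3,  646.6, 510, 16, 8, 0.37, 3.00, 1.86, 0.24, 0.37, 0.48),
    ("06", 2300.1, 41.5, 1357.1, 610,  6, 3, 0.11, 2.40, 1.59, 0.18, 0.34, 0.59),
    ("07", 2300.1, 13.5,  823.4, 585,  2, 3, 0.11, 2.80, 1.72, 0.01, 0.34, 0.98),
    ("08", 2299.6, 29.3, 2441.3, 505, 30, 1, 0.00, 1.40, 1.07, 0.00, 0.05, 1.00),
    ("09", 2300.1, 88.8, 1637.4, 345,  1, 6, 0.26, 2.60, 1.88, 0.27, 0.38, 0.43),
    ("10", 2299.6, 37.0,  958.4, 430, 90, 2, 0.05, 2.20, 1.51, 0.01, 0.29, 0.97),
    ("11", 2300.1, 49.0, 1431.7, 320,  9, 2, 0.05, 2.20, 1.48, 0.20, 0.28, 0.36),
    ("12", 2300.1, 24.6,  751.0, 535, 30, 4, 0.16, 2.40, 2.12, 0.23, 0.44, 0.53),
    ("13", 2300.0, 30.8, 1000.1, 395, 41, 3, 0.11, 2.20, 1.48, 0.05, 0.26, 0.83),
    ("14", 2299.4, 11.3,  940.2, 230,  4, 3, 0.11, 2.00, 1.27, 0.06, 0.18, 0.56),
    ("15", 2299.6, 10.4,  826.1, 225,  1, 3, 0.11, 2.00, 1.54, 0.17, 0.23, 0.25),
    ("16", 2299.4, 19.7,  908.0, 260, 34, 1, 0.00, 1.40, 1.33, 0.00, 0.18, 1.00),
]

#: number of ramets sampled per plot in the survey design
SAMPLES_PER_PLOT = 20


def carex_fen_environment() -> list[PlotEnvironment]:
    """The 16 plot environments (elevation, P, K, shoot counts)."""
    return [PlotEnvironment(r[0], r[1], r[2], r[3], r[4], r[5])
            for r in _FEN_ROWS]


def carex_fen_diversity() -> list[PlotDiversity]:
    """The 16 published per-plot diversity records."""
    return [
        PlotDiversity(plot_id=r[0], elevation=r[1], P=r[2], K=r[3], Ss=r[4],
                      Sf=r[5], G=r[6], R=r[7], Na=r[8], Ne=r[9], Ho=r[10],
                      He=r[11], F=r[12])
        for r in _FEN_ROWS
    ]
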