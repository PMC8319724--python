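"""Conservation of a psychiatric risk-gene set vs genome backgrounds.

Builds the printed-count fixture (336 risk genes; 276 with C. elegans
counterparts, 324 with zebrafish counterparts), tallies conservation, and
tests each tally against the genome-wide ortholog rate with a two-cell
chi-square goodness of fit.
"""

from consynt import chi_square_gof, paper_count_fixture, tally_conservation

fixture = paper_count_fixture()

for species in ("celegans", "zebrafish"):
    tally = tally_conservation(fixture.assignments(species))
    K, N = fixture.backgrounds_conservation[species]
    res = chi_square_gof(tally.with_counterpart, tally.total, K, N)
    print(
        f"{species:10s} risk {tally.with_counterpart}/{tally.total} "
        f"({tally.percent:.1f}%) vs genome {K}/{N} ({100 * K / N:.1f}%)  "
        f"chi2={res.chi2:.1f}  p={res.p_value:.2e}  {res.direction}"
    )

# The risk set is far more conserved than the genome at large: a gene set
# this skewed toward ancient, retained genes is what the enrichment flags.
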