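# SR-protein ESE matrices (synthetic stand-ins)

These position weight matrices for the SR splicing factors SRSF1, SRSF2,
SRSF5 and SRSF6 are **synthetic stand-ins built for this package**: they
are consensus-anchored log-odds-style weight tables, not the published
SELEX-derived ESEfinder matrices, which are not redistributed here.

Each `<factor>.tsv` has a header row `pos  A  C  G  T`; a window's score
is the sum of per-position weights, and a hit passes when the score
reaches the factor's threshold in `thresholds.tsv`.

Design anchors (the consensus word scoring highest under each matrix):

| factor | width | consensus anchor | threshold |
|--------|-------|------------------|-----------|
| SRSF1  | 7     | GGAAGAA          | 6.2       |
| SRSF2  | 7     | CAGCAGA          | 5.8       |
| SRSF5  | 7     | TCACAGG          | 6.1       |
| SRSF6  | 6     | TGCGTC           | 5.0       |

The SRSF2 table is calibrated so the documented CAGCAGA>CAGTAGA point
substitution crosses the threshold downward ("disrupted"), matching the
qualitative behaviour expected of an SRSF2-bound exonic splicing enhancer.
Absolute scores are not comparable to any external tool's output.
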