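# pooldeconv

Five-dimensional BAC clone pooling: design construction, pool-hit
deconvolution against a fingerprint contig map, a seeded simulator, and
evaluation metrics.

Large BAC libraries are screened as pools rather than as individual clones: a
stack of 384-well plates is pooled into plate pools (PP), the plate pools
into a 2-D matrix of row/column super-pools (RSP/CSP), and the wells into
clone row/column pools (RP/CP) split per library into sub-pools of ~1–2×
genome coverage. A marker assayed against the pools yields positive pool
identifiers; the true positive clones sit at intersections of those pools,
among many false intersections. `pooldeconv` resolves them by exhaustively
searching every contig of a fingerprint contig map for candidate clones that
are fingerprint neighbours (containment, spanning, or overlap), scoring each
clone set with `0.8*NC/MC + 0.2*(1 - FN/NC)`, and reporting the best set as
the marker's clones (unique / non-unique / no solution).

## Modules

| module                      | contents                                                             |
| --------------------------- | -------------------------------------------------------------------- |
| `pooldeconv.design`         | plate layouts, libraries, the super-pool matrix, sub-pools, clone-name grammar, pool sizing and reverse lookup |
| `pooldeconv.fpc_io`         | minimal textual FPC dialect, sidecar band files, pool-hit / matrix-design / truth TSVs, summary + anchored + ACE-style writers |
| `pooldeconv.deconvolution`  | candidate generation, fingerprint relations, C2 search, FN counting, scoring, per-marker deconvolution |
| `pooldeconv.simulate`       | seeded synthetic genomes, interval clones, band-site fingerprints, perfect contigs, markers, error-injected pool hits, contig degradation |
| `pooldeconv.evaluate`       | marker classification, recall/precision, per-pool-kind F+/F− hit rates, error-rate estimation |
| `pooldeconv.cli`            | `pooldeconv` command group wiring all of the above                   |

## CLI

```sh
# build a pooling design from a library table (TSV: code, n_plates, genome_coverage)
pooldeconv design --libraries libraries.tsv --rows 27 --cols 30 --outdir design/

# generate a synthetic fixture bundle from a YAML config
pooldeconv simulate --config sim.yaml --seed 4 --outdir bundle/

# deconvolute a pool-hit file against a contig map
pooldeconv deconv --design bundle/design.yaml --matrix bundle/matrix.tsv \
    --fpc bundle/map.fpc --hits bundle/hits.tsv --outdir results/

# score against simulation truth (adds per-pool hit rates when hits+design given)
pooldeconv evaluate --summary results/summary.tsv --truth bundle/truth.tsv \
    --hits bundle/hits.tsv --design bundle/design.yaml --matrix bundle/matrix.tsv \
    --outdir metrics/

# convert an anchored-marker table to the ACE-style marker merge file
pooldeconv convert-ace --anchored results/anchored.tsv --out markers.ace
```

Exit codes: `0` success, `2` usage/config error, `3` input parse error.
Algorithm knobs on `deconv`: `--tolerance` (band match tolerance),
`--min-shared` (overlap threshold), `--no-library-filter` (idealized
intersection arithmetic without sub-pool plate filtering).

A simulation config looks like:

```yaml
genome_length: 230400.0
band_site_density: 1.0
libraries:
  - {code: LA, n_plates: 1, insert_mean: 100.0, insert_sd: 10.0}
  - {code: LB, n_plates: 1, insert_mean: 100.0, insert_sd: 10.0}
n_markers: 100
seed: 4
matrix_shape: [10, 10]
p_fp: 0.0        # scalar or per-kind map {RSP: ..., CSP: ..., RP: ..., CP: ...}
p_fn: 0.0
min_tp_per_marker: 2
```

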