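# borderindel

Models of how deletion-biased indel mutation shapes the lengths of neutral
genomic sequences that sit between conserved regions — and why such
sequences (introns, most prominently) are not eroded away even though
deletions outnumber insertions.

The central mechanism is **border-induced selection**: a deletion whose
footprint would protrude from the neutral segment into its conserved flanks
is removed by purifying selection. Of the `L` anchored placements of a
`d`-bp deletion in an `L`-bp segment, only `L-d+1` stay inside, so a
proposed deletion survives with probability

    p_valid = max((L - d + 1) / L, 0),

and short segments become effectively insertion-biased even when the
genome-wide ratio

    r = (p_ins * mu_i) / (p_del * mu_d)  <  1

favours deletions. The package implements the resulting model hierarchy:

* **M1** — unit indels; stationary length is geometric with mean `r/(1-r)`;
* **M2** — fixed indel sizes `mu_i`/`mu_d`; stationary mean
  `(r + mu_d - 1)/(1 - r)` away from the short-length boundary;
* **M3** — indel lengths drawn from a truncated Zipfian law
  `f(k) = k^-a / sum_{i<=m_max} i^-a` (default `m_max = 150`);
* **M4** — M3 plus conserved structure: edge length `le`, and with
  probability `pc` one internal conserved segment of length `li` that
  splits the intron into two independent neutral stretches.

It provides, per component: exact small-chain stationary solvers and closed
forms (`analytic`), an event-skip stochastic simulator of stationary length
distributions with empirical convergence verification (`simulator`, `m4`),
log-scale histogram machinery and GFF3 intron extraction (`empirical`),
grid-search and trust-region fitting of the models to observed length
distributions (`fitting`), and seeded synthetic-data generators
(`fixtures`). A `borderindel` command-line tool wraps simulation, fitting
and fixture generation.

## Worked example

Simulate the stationary intron-length distribution at the parameters fitted
to human introns under M3 (`r = 0.983`, `p_del = 1e-7`, mean insertion
16.5 bp, mean deletion 4.5 bp):

```bash
borderindel simulate --model M3 --r 0.983 --pd 1e-7 \
    --mu-i 16.5 --mu-d 4.5 --n 2000 --seed 1 --out m3_lengths.tsv
```

which prints

```
wrote 2000 stationary lengths to m3_lengths.tsv (mean 1708.5 bp, s.d. 2343.5 bp)
```

A mean near 1700 bp with a standard deviation of similar magnitude is the
signature of this regime: the distribution is broad and right-skewed, with
its log10-density mode near 2100 bp — but it is unimodal, unlike the
empirical human intron distribution. Adding conserved structure (M4 with
`le = 88`, `li = 35`, `pc = 0.69` on base ratio `r = 0.9776`) raises the
mean above 2000 bp and creates the second log-scale mode near 100 bp:

```python
from borderindel import (IndelModelParams, M4Params, SimulationConfig,
                         simulate_m4, summarize)

m3 = IndelModelParams.m3(0.9776, 1e-7, 16.5, 4.5)
sample = simulate_m4(m3, M4Params(le=88, li=35, pc=0.69),
                     SimulationConfig(n_replicates=1500, seed=1))
s = summarize(sample)
print(f"mean {s.mean:.0f} bp, s.d. {s.sd:.0f} bp, "
      f"log10 mode {s.mode_log10:.2f}")
# mean 2101 bp, s.d. 2285 bp, log10 mode 3.38
```

To fit a model to your own lengths (one integer per line, or a GFF3
annotation with `--gff3`):

```bash
borderindel fit --model M3 --empirical lengths.txt \
    --pd 1e-7 --mu-i 16.5 --mu-d 4.5 --n-per-eval 10000 --seed 1 \
    --out fit.json
```

The JSON output contains the best `r`, its mean-squared error between the
simulated and observed log10-length densities, and the full `(r, MSE)`
grid.

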