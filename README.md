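# tetracross

Tetrad analysis of meiotic crossing-over in budding yeast: genetic map
distances, crossover interference and crossover assurance from four-spore
tetrad genotypes, strain phenotyping (spore viability, meiosis I
nondisjunction, gene conversion), arithmetic over quantified recombination
intermediates, and a forward meiosis simulator to calibrate all of it.

It is written for geneticists dissecting tetrads — the four haploid spores of
one yeast meiosis — and scoring ordered markers along a chromosome, and for
anyone modelling how crossover control (interference, assurance, homeostasis)
shapes those data.

## What it computes

For a pair of linked markers, tetrads fall into three classes: parental
ditype (PD), tetratype (TT) and non-parental ditype (NPD, which requires a
four-strand double crossover). From per-interval tallies the package
computes:

* **Perkins map distance** — cM = 100·(6·NPD + TT) / (2·(PD + NPD + TT)),
  which corrects for double crossovers, with a multinomial delta-method
  standard error;
* **NPD-ratio interference** — the expected NPD frequency without
  interference given the tetratype frequency fT is the Papazian expression
  NPD<sub>exp</sub> = ½[(1 − fT) − (1 − 3fT/2)<sup>2/3</sup>]; observed/expected
  ratios significantly below 1 (one-sided exact binomial test) indicate
  positive crossover interference;
* **adjacent-interval interference** — tetrads are split by whether a
  reference interval has a crossover (Adj<sup>CO</sup>) or not
  (Adj<sup>PD</sup>) and the test interval is mapped within each subset;
  cM<sup>AdjCO</sup>/cM<sup>AdjPD</sup> < 1 means interference (permutation
  test, ratios averaged over the two directions);
* **crossover classes and assurance** — minimal crossover counts per tetrad
  (PD→0, TT→1, NPD→2 per interval) give the E0, E1, … distribution; the
  zero-crossover class is tested against the Poisson null
  P(E0) = e<sup>−mean</sup>, with mean crossovers = total cM / 50;
* **E0 purging** — removing non-exchange tetrads before interference
  analysis, which undoes the dilution of interference signals caused by an
  achiasmate subpopulation;
* **phenotypes** — viable-spore distributions, disome detection via BOTH
  calls at centromere-linked markers (meiosis I nondisjunction), and gene
  conversion (3:1/1:3 segregation) cross-tabulated against E0 status;
* **molecular ratios** — interhomolog/intersister (IH/IS) double-Holliday-
  junction ratios, crossover fraction p ↔ CO/NCO ratio p/(1−p), and a
  crossover-bias compensation model that asks how much of a homolog-bias
  defect is offset by an elevated crossover fraction.

The simulator (`tetracross.sim`) generates tetrads under a Poisson or
counting-model (chi-square renewal) crossover process with optional obligate
crossover, assurance-failure mixtures, per-marker gene conversion, backup
segregation of achiasmate bivalents, and spore death — together with a
per-meiosis truth record that classification-independent oracles are built
from.

## Worked example

```python
import tetracross as tc

config = tc.wild_type_like(n_tetrads=2000, seed=1)
result = tc.simulate_tetrads(config)
tallies = tc.tally_intervals(result.tetrads, config.map)
for iv, tal in list(tallies.items())[:2]:
    est = tc.perkins_cM(tal)
    print(iv, tal.PD, tal.TT, tal.NPD, round(est.cM, 1), round(est.se_cM, 2))
```

prints

```
('CHA1', 'TRP1') 1212 344 0 11.1 0.53
('TRP1', 'HIS4') 1135 421 0 13.5 0.56
```

— per interval: the PD/TT/NPD tally among the 4-viable-spore, fully
Mendelian tetrads, and the Perkins estimate with its standard error; the
nine-marker map totals ≈131.6 cM (≈2.6 crossovers per meiosis). The
`examples/` directory holds one short script per capability
(`simulate_and_map.py`, `interference_and_purging.py`,
`assurance_and_phenotypes.py`, `molecular_ratios.py`); each prints its
numbers with a line on what they mean. A thin CLI mirrors the same stages:

```sh
tetracross simulate --config sim.yaml --out-dir out/
tetracross map out/tetrads.tsv map.tsv
tetracross interference out/tetrads.tsv map.tsv --purge-e0
```

File formats (tetrad table, marker map, quant table — all TSV) are
documented with grammars in `tetracross/io.py`.

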