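# satdyn — multilevel dynamics of satellite plasmids

Multicopy broad-host-range plasmids of the IncQ family (RSF1010-like) carry
their replication machinery (*repA/B/C*) separately from their replication
origin (*oriV*). A single deletion can therefore produce a **satellite
plasmid (SP)**: a nonautonomous miniplasmid that keeps *oriV* but loses the
replication genes, the selected marker (*aadA*) and the burdensome accessory
genes (*gfp*, *lacI*), and parasitizes the replication proteins of the
full-length plasmid that remains in the same cell. Satellite plasmids
lower the cost of plasmid carriage while keeping copies of the accessory
genes around — a transient evolutionary intermediate between "newly acquired
plasmid" and "accessory genes lost".

`satdyn` is a research toolkit for asking *why satellite plasmids arise
preferentially* over the obvious alternative, an autonomous plasmid that
deletes only the accessory genes (**deletion plasmid, DP**). It provides:

* a **within-cell layer**: plasmid species with additive per-copy fitness
  costs, exact doubling of the plasmid pool at division (equal replication
  chances for every copy; stochastic urn variants available as switches),
  and random-but-even assortment of the doubled pool to daughters
  (multivariate hypergeometric) — daughters left without a marker-bearing
  plasmid die under selection;
* a **population layer**: serial-dilution competition of the focal cells
  against a fixed-fitness background, with three protocols — tuning the
  background fitness until the focal population is demographically stable
  (its realized equilibrium fitness), phenotypic-delay fitness trajectories
  of newly arisen mutant plasmids, and single-founder establishment
  probabilities under daily bottlenecks;
* a **microhomology scanner**: every maximal pair of near-perfect direct
  repeats on a circular replicon (≥7 bp, ≤1 indel, ≤5 total mismatches
  including indels, ≥75% identity), overlap resolution (longest first, then
  fewest mismatches), cross-region counting, and deletion-junction
  annotation;
* **deletion-endpoint combinatorics**: closed-form counts of all (start,
  end) coordinate combinations whose deletion yields an SP or a DP on an
  annotated circular map, and their ratio (the mutational-target bias);
* a **synthetic-data module** (random circular plasmids with planted
  near-repeats, miniature annotated maps, bundled study presets) so that
  every stage is testable without downloads.

## The model in brief

A newborn cell holds `N = 18` plasmid copies across species `s` with
per-copy costs `c_s`; its relative fitness is `w = max(0, 1 − Σ_s n_s c_s)`
with `c_FL = 0.0306` (full-length), `c_DP = 0.0050`, `c_SP = 0` — costs that
reproduce the measured fitness of pure carriers (e.g. `1 − 18·0.0050 =
0.910`). Time is counted in doublings of a background population of fitness
`w_b`. Per background doubling a cell's lineage must grow by `2^(w/w_b)` in
expectation (so that relative fitness is the Malthusian-parameter ratio
measured in competition assays); each generation is split into `S = 8`
sub-steps in which a cell divides with probability `2^((w/w_b)/S) − 1`.
Dividing cells double their plasmid pool exactly and assort it evenly at
random; under selection, daughters that inherit no marker-bearing plasmid
are removed. Serial transfer is binomial thinning by the dilution factor.

The key emergent numbers: satellite carriers equilibrate near 5 full-length
+ 13 satellite copies per cell; their realized fitness (~0.77) falls short
of the additive expectation for that burden (~0.84) because of marker-free
segregant death; a new SP's descendants out-compete a new DP's for the
first ~12–13 generations (reduced phenotypic delay), giving the SP a ~17%
establishment advantage under daily 1:2000 transfers, on top of a severalfold
larger deletion-endpoint target.

## Worked example

Tune the background fitness for satellite carriers and read off the
equilibrium (reduced desk preset; the full preset uses 10,000 cells and 500
generations):

```console
$ satdyn equilibrium --desk --seed 5 --out eq.tsv
equilibrium fitness 0.7751; composition ancestral=5.15, satellite=12.85
```

The tuned background fitness (0.775) *is* the satellite carriers' realized
equilibrium fitness; 5.15/12.85 are the mean full-length/satellite copies
per cell. Phenotypic delay and establishment:

```console
$ satdyn delay --desk --seed 2 --out delay.tsv
satellite advantage lasts 12 generations
$ satdyn establish --desk --seed 2 --trials 200000 --out est.tsv
establishment advantage of satellite over deletion: 21.9%
```

`delay.tsv` holds the per-generation mean realized fitness of both mutant
types with 95% bands (satellite starts higher: one cost-free SP copy beats
one 0.5%-cost DP copy; deletion carriers overtake later en route to 0.910
while satellites plateau at ~0.77). The establishment table lists
per-mutant establishment frequencies with Wilson intervals; at this desk
scale the 21.9% excess carries a wide interval that comfortably covers the
full-scale value (~17%).

Sequence side — make a synthetic annotated plasmid, scan it, and count
deletion opportunities:

```console
$ satdyn synth --length 2000 --plant 9,120,800,0,0 --seed 7 --out-prefix plasmid
$ satdyn repeats plasmid.fasta --out repeats.tsv
59 repeats written to repeats.tsv
$ satdyn delspace plasmid.map.tsv
satellite-forming deletions: 56640
accessory-deletion deletions: 78638
SP:DP ratio: 0.72
```

(The toy map's geometry differs from the real plasmid's, hence a ratio
below 1; on the published pQGS annotation — GenBank MH423581, readable with
`satdyn delspace pQGS.gb` — the same arithmetic yields the ~4:1 bias toward
satellite formation.)

## Layout

```
src/satdyn/
  cell.py        within-cell species, fitness, replication, segregation
  population.py  serial-dilution protocols (tuning, delay, establishment)
  _engine.py     exact aggregated-state samplers behind the protocols
  repeats.py     microhomology scanner and junction annotation
  delspace.py    deletion-endpoint classification and counting
  synth.py       synthetic plasmids, toy maps, study presets
  io.py, cli.py  GenBank/TSV/BED boundaries and the satdyn CLI
docs/methods.md  modelling assumptions, parameters, numerical choices
```
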