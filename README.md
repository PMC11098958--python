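# allopath

Allosteric path analysis of protein Cα trajectories via structural-alphabet
mutual-information networks, plus a FRET-lifetime / Hill-titration fitting
arm. Built for studies of long-range coupling in membrane transporters —
the motivating case is the Ca²⁺ pump SERCA, where nucleotide binding at the
N-domain allosterically raises Ca²⁺ affinity at the transmembrane binding
sites and the micropeptide phospholamban suppresses that activation — but
every stage is generic.

## What it computes

**Network arm.** A protein of n residues is decomposed into n − 3
overlapping 4-residue fragments; each fragment's conformation in each
trajectory frame is assigned a letter of a structural alphabet (by minimal
RMSD against canonical 4-point fragments, or by nearest (θ1, θ2, τ)
pseudo-bond/torsion descriptors). Columns of the resulting string
alignment are compared by normalized mutual information

&nbsp;&nbsp;&nbsp;&nbsp;I_LLn(C_i; C_j) = ( I(C_i; C_j) − ε(C_i; C_j) ) / H(C_i, C_j),

with ε = (B_ij − B_i − B_j + 1)/(2T) the first-order finite-size bias term
(B = occupied histogram cells, T = frames). Fragments within a distance
cutoff (default 30 Å between time-averaged first Cα positions) whose I_LLn
exceeds a cutoff (default 33% of the maximum off-diagonal value) are
linked by an edge of weight w = 1 − I_LLn. Allosteric paths between two
binding-site fragment sets are minimum-total-weight Dijkstra paths over
all site-pair combinations; node importance is eigenvector centrality of
the I_LLn-weighted adjacency; I_LGn couples each fragment to discretized
global collective-motion states (first principal component,
equal-frequency bins).

**Spectroscopy arm.** TCSPC photon-count histograms (16 ps bins) are
tail-fit with 1–2 exponentials by Poisson maximum likelihood; the
amplitude-weighted lifetime τ_DA = Σaᵢτᵢ/Σaᵢ and donor-only τ_D give the
FRET efficiency E = 100·(1 − τ_DA/τ_D). FRET-vs-[Ca²⁺] titrations are fit
globally with the Hill model y = START + (END − START)·xⁿ/(Kⁿ + xⁿ), one
shared Hill coefficient n and per-condition START/END/K; binding constants
are compared by one-way ANOVA with Šidák-corrected pairwise t tests.

A `synthetic` module generates every input class with known ground truth
(planted coupled fragment chains, two-state hinged polymers with 15/20 Å
probe distances, Poisson decays, noisy Hill titrations), so the whole
pipeline is testable without any experimental data.

## Worked example

```python
from allopath.synthetic import PlantedChainSpec, TitrationSpec, \
    write_chain_fixture, write_titration_fixture
from allopath.pipeline import RunConfig, run_path_analysis, run_fret_analysis

write_chain_fixture(PlantedChainSpec(seed=1), "demo/chain")
report = run_path_analysis(RunConfig(
    out_dir="demo/run",
    alignment_path="demo/chain/strings.txt",
    coords_path="demo/chain/coords.csv",
    site_a=[0], site_b=[6],
))
print(" -> ".join(f"f{f}" for f in report.fragments), report.total_weight)
```

prints

```
f0 -> f1 -> f2 -> f3 -> f4 -> f5 -> f6 2.7094
```

i.e. the recovered allosteric path is exactly the planted 7-fragment
chain: the per-edge I_LLn of its six links is ≈ 0.55 (strong coupling →
edge weights ≈ 0.45, total cost 2.71), while every off-chain fragment pair
falls below the MI cutoff (0.185 = 33% of the maximum) or the 30 Å
distance gate. Fitting a synthetic four-condition titration the same way:

```python
write_titration_fixture(TitrationSpec(seed=1, replicates=4), "demo/tit")
out = run_fret_analysis(RunConfig(out_dir="demo/frun",
                                  titration_path="demo/tit/titration.csv", seed=1))
```

gives a shared Hill coefficient n = 0.857 ± 0.102 (truth 1.0) and

```
apo                        K = 1857.6 nM   (truth 1800 nM)
nucleotide                 K =  309.9 nM   (truth  332 nM)
nucleotide+inhibitor       K =  662.3 nM   (truth  702 nM)
nucleotide+phosphomimetic  K =  345.4 nM   (truth  334 nM)
```

with one-way ANOVA F = 9.84, p = 1.5e-3 across per-replicate K values —
the qualitative signature of nucleotide activation (K drops ~5-fold),
its reversal by the inhibitory peptide (K doubles back), and relief of
inhibition by the phosphomimetic mutant.

The same flows are available from the shell:

```bash
allopath simulate chain --out demo/chain --seed 1
allopath path --alignment demo/chain/strings.txt --coords demo/chain/coords.csv \
              --site-a 0 --site-b 6 --out demo/run
allopath simulate titration --out demo/tit --seed 1
allopath hill --table demo/tit/titration.csv --out demo/frun
```

## Acceptance script

`scripts/acceptance.py` re-runs both pipelines from scratch on the
synthetic stated world — it generates a planted-chain fixture, recovers
the allosteric path through the full encode → I_LLn → network → Dijkstra
stack, then simulates decay histograms and a four-condition titration and
runs the lifetime-fit → FRET → global-Hill → ANOVA stack — and writes its
results JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `allopath.io` — PDB/DCD/XTC reading and writing, Cα selection
- `allopath.geometry` — superposition, RMSF, pair distances, 2D density maps
- `allopath.alphabet` — fragments, descriptors, `StructuralAlphabetEncoder`
- `allopath.infonet` — I_LLn, `AllostericNetwork`, Dijkstra paths, centrality, I_LGn
- `allopath.fret` — `DecayModel`, FRET efficiency, `GlobalHillModel`, K comparisons
- `allopath.synthetic` — ground-truth generators and fixture writers
- `allopath.pipeline` / `allopath.cli` — orchestration, manifests, `allopath` CLI

See `docs/methods.md` for the model assumptions, parameter defaults, and
numerical choices.
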