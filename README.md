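# maefmd — multi-agent evolutionary detection of protein functional modules

Proteins carry out cellular functions in groups — functional modules or
complexes — that appear as densely interconnected subgraphs of a
protein-protein interaction (PPI) network. `maefmd` detects such modules by
evolving a population of *agents*, each encoding one candidate partition of
the network, on a toroidal lattice. It is aimed at computational biologists
who want a modularity-driven, annotation-aware complex detector together
with the standard evaluation metrics, usable as a Python library or from
the shell.

## The method

**Encoding.** An agent is a connection vector `A = ((1→a_1), …, (N→a_N))`
with `a_i ∈ Γ(i) ∪ {i}`: every node points at one of its interaction
partners or at itself (a *breakpoint*). Connected components of these links
are the modules, so the number of modules K is never fixed in advance.

**Construction.** Each agent builds its vector by random walks. From node
*i* the walk steps to a neighbor *j* with probability proportional to the
combined connection strength

    s_ij + f_ij ≥ ε,
    s_ij = |Γ⁺(i) ∩ Γ⁺(j)| / √(|Γ⁺(i)|·|Γ⁺(j)|)      (closed neighborhoods)
    f_ij = |g^i ∩ g^j|² / (|g^i|·|g^j|)               (GO term sets)

skipping nodes already visited in the current traversal; with no feasible
step the walk ends at a breakpoint and restarts elsewhere.

**Evolution.** Agents live on an m×m torus (M = m² agents) and interact
only with their four lattice neighbors. Partition quality is the modularity
"energy" `Energy(A) = Σ_c [e_c/|E| − (d_c/2|E|)²]` over decoded modules.
Each iteration applies, per cell: *competition* (a losing agent's cell is
occupied by a clone of its best neighbor, improved with the loser's
stronger links), *crossover* (alternating-link and alternating-chunk rules
against a random neighbor, keeping a child only if strictly better) and
*self-adaptive mutation* (the number of mutated digits grows with network
size and stagnation time). The run stops once the best energy has
stagnated for R iterations.

**Post-processing.** Functionally close modules (symmetric best-match
similarity > λ) are merged; modules smaller than two proteins or with
induced density 2e_s/(n_s(n_s−1)) < δ are filtered out.

**Evaluation.** Predictions are matched to reference complexes with the
neighborhood affinity `NA(p,b) = |p∩b|²/(|p|·|b|)` at threshold ω (0.2),
giving precision/recall/F-measure; clustering-wise Sn/PPV/Acc come from
the overlap matrix `T_ij`; per-module functional homogeneity uses the
hypergeometric tail p-value.

## Worked example

```sh
$ python examples/detect_on_synthetic.py
network: 60 proteins, 322 interactions
best energy 0.6034 after 61 iterations
6 preliminary -> 6 final modules
vs truth: precision=1.000 recall=1.000 F=1.000 Sn=1.000 PPV=1.000 Acc=1.000
```

Sixty proteins in six planted modules (within-module interaction
probability 0.9, between 0.05, 10% annotation noise) are recovered
exactly: the best evolved partition's modularity (0.6034) equals that of
the ground truth, and all six complex-wise and clustering-wise scores are
perfect. The bundled anaphase-promoting example behaves the same way:

```sh
$ python examples/anaphase_worked_example.py
predicted module: 13 proteins
curated complex:  16 proteins
overlap:          13 proteins
NA score:         0.8125
matching rate:    100.0%
```

All 13 proteins of the detected module belong to the curated 16-protein
anaphase-promoting complex.

The same workflows run from the shell:

```sh
maefmd simulate --nodes 60 --modules 6 --seed 1 --out case/
maefmd detect --network case/network.tsv --annotations case/annotations.tsv \
              --preset dip --seed 1 --out run/
maefmd evaluate --predicted run/modules.txt --reference case/truth_complexes.txt \
                --network case/network.tsv --out eval/
```

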