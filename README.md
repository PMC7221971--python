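# graphppi

Sequence-based prediction of protein–protein interactions (PPIs) from
amino-acid sequences alone, using **graph-energy descriptors** and a
**weighted sparse representation classifier**.

Experimentally mapping interactomes is slow and noisy, so computational
screens that need nothing but the two sequences are widely used to
prioritise candidate interactions. `graphppi` implements one such pipeline
for bioinformaticians who want a self-contained, reproducible
implementation: every stage (encoding, reduction, classification,
evaluation) is a plain library call, and a synthetic-data module generates
benchmark datasets with a plantable interaction signal so the whole
pipeline can be validated without downloading any external resource.

## Method

**Per-protein encoding.** Fix the 20 canonical residues in a
physicochemical order (descending isoelectric point / ionization
equilibrium constant): D, E, C, N, M, F, Q, Y, S, P, T, V, L, I, W, H, G,
A, R, K. A protein of length *n* becomes a 20 × *n* matrix whose column
*j* is the substitution-matrix column of residue *j*. A window of 20
consecutive columns is a biadjacency matrix *M_k* of a bipartite graph;
its **graph energy** is the sum of the absolute eigenvalues of the full
adjacency

    E(G_k) = Σ_i |λ_i|  of  [[0, M_k], [M_kᵀ, 0]]  =  2 Σ_i σ_i(M_k),

i.e. twice the nuclear norm of the window. Sliding the window one residue
at a time gives an energy profile, fixed at 200 entries (zero-padded below
219 residues, truncated above). Two substitution matrices give two
profiles: the identity in the physicochemical basis (physicochemical graph
energy, PGE) and a real-valued amino-acid contact-energy matrix (contact
graph energy, CGE). A third block is the dipeptide composition
f_mn = N_mn / (L−1) over all 400 ordered residue pairs. The fused
descriptor is [PGE; CGE; dipeptide] ∈ R⁸⁰⁰.

**Reduction and pairing.** Fused descriptors are PCA-reduced to d = 80
dimensions (d = 20 in cross-species mode); a protein pair is the
concatenation of its two reduced vectors.

**Classification.** A test pair *y* is coded over the dictionary *X* of
L2-normalised training pairs by weighted basis-pursuit denoising,

    β̂ = argmin ‖Wβ‖₁  subject to  ‖y − Xβ‖₂ ≤ ε,

with locality weights W = diag(w_i), w_i = 1 / exp(−‖y − x_i‖²/(2σ²)),
so far-away training pairs are expensive to use. The pair is labelled
interacting or not by the class whose columns reconstruct it with the
smallest residual ‖y − Xβ̂_c‖₂. The problem is solved exactly by the
lasso homotopy path with interpolation onto the residual constraint.

**Evaluation.** Stratified five-fold cross-validation with accuracy,
sensitivity, precision, Matthews correlation coefficient and rank-based
AUC; PCA is fitted on each training fold's proteins only.

The packaged contact matrix (`graphppi/data/contact_energy_synthetic.tsv`)
is a deterministic **synthetic stand-in** on the scale of statistical
contact energies; substitute a real contact-energy matrix via
`--contact-matrix` / `load_contact_matrix` for biological work.

## Worked example

Generate a synthetic benchmark (100 interacting + 100 non-interacting
pairs, lengths 120–250, compositional signal strength δ = 0.5) and
cross-validate the full pipeline:

```sh
graphppi simulate --out-dir demo --seed 1
graphppi train-eval --fasta demo/proteins.fasta --pairs demo/pairs.tsv \
    --seed 1 --out demo/report.tsv
```

which prints

```
Testing Set   ACC  SEN      MCC      Pre    AUC
     fold 1 0.925 0.90 0.851064 0.947368 0.9850
     fold 2 0.900 0.90 0.800000 0.900000 0.9700
     fold 3 0.975 0.95 0.951190 1.000000 1.0000
     fold 4 0.850 0.75 0.714435 0.937500 0.9575
     fold 5 0.950 0.95 0.900000 0.950000 0.9800
    Average 0.920 0.89 0.843338 0.946974 0.9785
```

Each row is one held-out fold; the planted compositional signal is
recovered with mean accuracy 0.92 and AUC 0.98. With `--delta 0` the
classes are statistically identical and accuracy drops to chance (≈0.5),
confirming the pipeline has no information leak. Other entry points:
`graphppi extract` writes the 800-column per-protein feature matrix, and
`graphppi predict` trains on one labelled set and scores another
(cross-species mode, d = 20). Every command writes its resolved
configuration as JSON next to its outputs.

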