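# Methods

`csmux` models a genetically encoded *channel selector* (CS): a
multiplexer (MUX) and demultiplexer (DEMUX) built from CRISPRi
transcriptional NOT/NOR gates in two bacterial strains, joined by an
acyl-homoserine-lactone (AHL) quorum-sensing wire, so that a single
communication channel can carry two separate small-molecule-controlled
conversations under a shared SELECT signal. This note records the models,
conventions, and numerical choices the package commits to, and what its
synthetic data can and cannot show.

## Logic synthesis

Gate networks are directed acyclic graphs over INPUT, NOT, and NOR nodes;
NOR(a, b, ...) = NOT(a OR b OR ...). Constant signals are not available
as inputs: in the transcriptional realization an absent promoter is a low
signal, and the only sources are the declared inputs.

`synthesize_minimal` performs iterative deepening on the total gate
count; each level is an exhaustive enumeration over fan-in-1 NOT and
fan-in-2 NOR gates reading any earlier signal, pruning gates that
duplicate an already-available Boolean function (sound for minimality:
consumers of a duplicate can be rewired and the gate deleted, giving a
strictly smaller matching network). The first level with a match is
therefore a proof that no smaller network exists. Ties among minimal
networks break by (fewer layers, fewer NOR gates, lexicographic canonical
netlist), making the result deterministic.

**Terminal-output convention.** By default output nodes may not feed
other gates. This is a biological commitment, not a Boolean one: each
output promoter drives its payload (a reporter or the conversation's
cargo), and routing it back into the logic would change the circuit
architecture. The convention matters: unconstrained enumeration finds a
3-gate DEMUX (`OUT1 = NOR(NOT(IN), S)`, `OUT2 = NOR(OUT1, NOT(IN))`) that
reuses OUT1 internally, whereas under the terminal-output convention the
minimum is the familiar 2 NOT + 2 NOR in 2 layers. Pass
`terminal_outputs=False` for the unconstrained electronic minimum.
Single-output tables are unaffected either way.

`build_cs_network` composes n-channel channel selectors constructively in
two styles and reports gate/layer/fan metrics from which scaling laws can
be read off. The *two_layer* style is flat product-of-sums NOR-NOR logic
with wide gates (a NOR with fan-in 1 + log2 n at level 1; biologically, a
promoter repressed by several sgRNAs); the *recursive* style is a tree of
the minimal fan-in-2 two-channel blocks. Both reduce to the same 8-gate
design (3 NOT + 5 NOR) at n = 2. No closed-form scaling laws are
asserted; the counts are computed from the built object.

## Gate and sensor models

Every signal is the reporter-equivalent output of a promoter in MEFL
(molecules of equivalent fluorescein), matching the probe-plasmid
measurement scheme in which each promoter of interest drives a
standardized sfGFP reporter; fitted transfer functions therefore compose
directly. Forms:

- NOT (repression):  y(x) = y_min + (y_max - y_min) / (1 + (x/K)^n)
- NOR:               y(x1, x2) = NOT(x1 + x2) — both input promoters
  transcribe the same sgRNA, so their fluxes add before the single
  repressor pool acts; the response is symmetric by construction.
- Sensor (activation): y(c) = y_min + (y_max - y_min) (c/K)^n / (1 + (c/K)^n),
  with c in inducer units (ng/ml aTc, mM IPTG, uM DAPG, nM AHL).

Parameters: y_min >= autofluorescence floor (MEFL), y_max (MEFL), K (same
units as the input), Hill coefficient n (dimensionless). An excess of
dCas9 and fast, stable dCas9:sgRNA complex formation are assumed
throughout, so repression depends only on the sgRNA-producing promoter's
output; dCas9 competition/saturation is deliberately out of the default
model and enters only as alternative parameter sets.

**Fitting.** Least squares on log10 output (fluorescence spans decades,
and the error metric is itself logarithmic), with y_min, y_max, K
optimized in log space. Bounds: y_min in [floor, min(y)], y_max in
[max(y), 10 max(y)], n in [0.5, 4]; K is multi-started at the 10/25/50/
75/90% quantiles of the positive inputs. The constrained fit pins n = 1;
the unconstrained fit additionally starts from the constrained optimum,
so its residual never exceeds the constrained one (proper nesting). Both
fits and their AICs are exposed (`compare_fits`); no preference rule is
hard-coded. Degenerate data (all outputs equal) return a flat curve with
K and n flagged unidentifiable. Parameter-recovery behavior: with the
default 7-point grid spanning both asymptotes, 0.05-decade noise and 3
replicates, all four parameters are typically recovered within ~15%.

## Circuit composition and dynamics

A circuit is a DAG of sensors, gates, AHL senders/receivers, and
reporters, with a strain label per node. Steady state is one topological
pass of the part models. Dynamics:

- Sensors are algebraic (small-molecule equilibration is fast relative to
  gate turnover; the DAPG sensor responds essentially immediately).
- Each gate or receiver output X relaxes first-order to its
  instantaneous Hill target f(upstream) at the strain growth rate
  lambda: dX/dt = lambda (f - X). Growth dilution of stable repressor
  and reporter is the only decay process — the slow CS computation
  time emerges from chaining these lags.
- AHL is shared and well mixed: dA/dt = k_prod * OD_sender * LuxI, with
  LuxI proxied by the MEFL of its driving promoter and
  k_prod = 0.089 nM/h/OD600/MEFL by default (the rate measured for LuxI
  senders with a receiver-strain biosensor). LuxI is treated as stable.
- ODs grow exponentially; media-replacement dilution events scale every
  strain's OD (and, by default, AHL — fresh medium contains none) by the
  retained fraction instantaneously. Intracellular MEFL states are
  unaffected by culture dilution.

Integration uses scipy's LSODA with rtol 1e-6, restarted at every
dilution event; outputs are recorded on a uniform internal grid (default
0.05 h) plus event boundaries. Trajectories are non-negative by
construction (states are clamped at zero when read).

Because AHL has no finite steady state under constant production,
`steady_state` reports a quasi-steady AHL = k_prod * OD * LuxI * window
(defaults: OD 0.2, window 1 h) unless the environment supplies an
explicit AHL concentration; the window is an explicit convention, not a
physical claim.

`estimate_ahl_rate` inverts the receiver's activating Hill curve to AHL
per supernatant sample and regresses it through the origin against the
trapezoidal integral of OD x LuxI; the slope is k_prod. Readouts at or
beyond the curve's asymptotes are excluded with a warning (a readout at
exactly the floor anchors zero). `activation_time` reports the first
rising half-threshold crossing (threshold relative to the node
trajectory's own min/max by default, with linear interpolation); falling
nodes report "never", since alternate layers of the path deactivate
rather than activate.

The reference topology (`csmux.reference`) wires the published
architecture: aTc/IPTG/DAPG sensors each route through one additional NOT
gate into the MUX (NOR5, NOT2, NOR6*, NOR3), OUT_MUX drives LuxI, and the
receiver strain's LuxR-activated promoter feeds the DEMUX (NOT8, NOR7,
NOT9, NOR2) with a second DAPG sensor through NOT3 as its SELECT. The
longest computation path counts eight layers — DAPG sensor, NOT4, NOT2,
NOR6*, NOR3, the AHL step (sender + receiver fused as one communication
event), NOT8, NOR7. The Hill parameters bundled with this topology are
representative synthetic values chosen for digital behavior at the
experimental doses; the published per-gate fit tables are not
redistributed, so predictions made with these defaults characterize the
model structure, not the measured strains.

## Guide library design

A pre-sequence is 15 random nt — the 3'-most 14 nt of a CRISPRi operator
(containing the specificity-conveying seed) plus the first, degenerate
PAM nucleotide — drawn at 40% GC (G/C 0.2 each, A/T 0.3 each). Appending
GG completes the NGG PAM; the 17-nt operator:PAM block exactly fills the
-35/-10 spacer of a scaffold promoter, and the 20-nt sgRNA operator is
the -35 hexamer plus the first 14 pre-sequence nt.

Construction filters: more than one additional NGG, or any additional
NAG, overlapping the inserted block (the designed PAM is the one
permitted addition) rejects the design, as does a BsaI site (GGTCTC,
either strand — Golden Gate incompatibility). Promoter PAM counting is
sense-strand only: those are the PAMs in the orientation an sgRNA uses to
repress this promoter, and both-strand counting would reject ~98% of
random 40%-GC candidates. Off-target screening against a genome scans
both strands (CRISPRi represses from either) with three ordered rules:
a >= 10-nt 3' match of the operator:PAM overlapping an essential feature;
a >= 12-nt 3' match anywhere; and any genomic site matching the 13-nt
seed exactly or with one mismatch immediately 5' of an NGG or NAG. The
first failing rule is reported. The seed rule is the operational
criterion the original CasValue screen enforced; full CasValue scoring is
not reimplemented.

Diversity selection works on the complete match graph (edge weight =
number of co-occurring nucleotides, 0-15). Phase 1 collects core_size
vertices from edges sorted by ascending weight (ties by index); phase 2
loops refinement_loops times over the excluded sequences, tentatively
adding each and discarding the member contributing the most matches, so
the total never increases. Candidate sets then grow from all pairs with
weight <= 5 by randomized expansion under the same cap (budgeted number
of attempts), and the final set minimizes the mean 3'-weighted edge score
(default weights 1..15 ascending toward the 3' end, punishing seed-region
matches; the exact published weights are unstated, so they are
configuration). Insulators are 70-nt random sequences rejection-sampled
against a compact forbidden-motif catalog (sigma-70 hexamers, strong
Shine-Dalgarno cores, common cloning sites, mononucleotide repeats, the
TetR O2 operator; both strands) — the full catalogs of the insulation
literature can be passed in — and are 5'-truncated so every insulated
promoter is exactly 105 bp.

## Synthetic cytometry

Single-cell FL1 is an additive autofluorescence draw (log-normal around
100 MEFL, 0.1 decades) plus a log-normal signal; FL3 (MECY) is log-normal
around a strain-specific mean; FSC/SSC are correlated log-normals that
exist only to exercise density gating (no optics model). Defaults — 0.2
decades population spread, 20,000-30,000 events — are fixture choices
representative of calibrated E. coli acquisition, not published
statistics. Transfer datasets apply multiplicative log-normal noise per
replicate and average three replicates in linear MEFL. Co-cultures mix
two strains by per-event Bernoulli draws at the nominal ratio (10:1 by
default). The orthogonality panel draws 9 x 9 fold changes around
on-/off-target levels (defaults 100 and 1).

What passing tests show: the estimators invert the generators — Hill
recovery, AHL-rate recovery, FL3 classification — under the generators'
idealized noise. What they do not show: correctness against real
measurements, where autofluorescence is non-log-normal, populations are
asymmetric, instrument drift exists, and the model forms themselves are
approximations. Wet-lab fluorescence magnitudes and the timing of the
real strains are outside what desk-scale synthetic data can certify.

## Evaluation conventions

- RMSE in MEFL decades: sqrt(mean((log10 pred - log10 meas)^2)); pairs
  containing a zero are omitted; an all-zero comparison is an error.
- Density gate: 2-D histogram on a 64 x 64 grid over (log FSC, log SSC);
  per-event density is the event's bin count; exactly round(0.85 n)
  events are retained by stable density ranking. A histogram was chosen
  over kernel estimates for determinism and reproducibility. Samples
  under 10 events pass through with a warning.
- FL3 classification: threshold in MECY (1,000 for sender/receiver
  monocultures, 600 for CS co-cultures); boundary equality goes to the
  high class (declared convention).
- Binning: frequency distributions use 64 log bins over the sample's
  recorded range with the modal bin normalized to 0.5; violins use 125
  bins from 10 to 1e6 MEFL (25 per decade) with floor(0.01 n) trimmed
  from each tail, per sample (whether the original trim was per sample
  or per panel is unstated; per sample is the documented choice). Mean
  fluorescence is always the arithmetic mean of linear MEFL, computed
  before trimming.
- Fold change is reported as repression fold, uninduced over induced
  (> 1 means repression) — a documented convention where the source
  axis is ambiguous.

## Problem sizes

The analysis drivers run at desk scale by design: 400 candidate
pre-sequences against a 100-kb synthetic genome with a 30-member core
(the published pipeline ran the same stages at 3,000 candidates, a
100-member core and four refinement loops over 2,900 exclusions — the
algorithms are identical, only the sizes differ), 5,000-event simulated
populations, and 12-13 h simulated protocols. The combinatorial
acceptance checks do run the full 3,000-sequence match graph
(4,498,500 edges), which is cheap because edge weights are computed
lazily.

## Known limitations

- The dCas9:sgRNA saturation fault observed for strongly induced AHL
  sensors, promoter-strength re-engineering (NOR6*, P_lux*), growth
  burden, and spatial effects are not mechanisms in the model; they can
  only be represented as alternative parameter sets.
- Gate dynamics use a single rate (the growth rate); fluorophore
  maturation delays and sgRNA-specific decay are not modeled.
- The terminal-output synthesis convention, the quasi-steady AHL window,
  the sense-strand PAM-counting rule, and the insulator motif catalog
  are declared package conventions where the source procedures are
  unstated or unavailable.
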