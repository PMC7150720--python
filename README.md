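# cardiolab

Multiscale cardiac electromechanics of the Kir2.1 **E299V** gain-of-function
mutation (short-QT syndrome type 3), from single-myocyte electrophysiology to
tissue-level conduction and whole-heart pump function.

The KCNJ2 E299V mutation impairs the inward rectification of the Kir2.1
channel, so the inward-rectifier current I<sub>K1</sub> — normally silent
during the action-potential plateau — becomes quasi-ohmic and large at
depolarized potentials. The package simulates the consequences of that single
molecular change across four scales:

1. **Myocyte** (`cardiolab.ionic_cell`, `cardiolab.protocols`) — a modified
   ten Tusscher–Panfilov human ventricular model with three I_K1
   current–voltage formulations (wild type `WT`, heterozygous `WT_E299V`,
   pure mutant `E299V`) and three transmural cell types (endo/mid/epi,
   G<sub>Ks</sub> = 0.392×1.3 mS/µF endo/epi, 0.073 mS/µF mid). Protocols:
   steady pacing, APD90, dynamic restitution, alternans detection.
2. **Myofilament** (`cardiolab.myofilament`) — a Rice-type cross-bridge
   cycle driven by the cytosolic calcium transient, producing normalized
   active force and the ATP-consuming detachment flux.
3. **Tissue** (`cardiolab.tissue`) — monodomain reaction–diffusion on
   desk-scale cables, rings and 2D sheets: conduction-velocity calibration
   (70 cm/s), activation/repolarization (EAT/EDT) maps with QRS/QT
   surrogates, S1–S2 cross-field stimulation and sustained ring reentry with
   wavelength measurement.
4. **Circulation** (`cardiolab.hemodynamics`) — a closed-loop eight-
   compartment lumped model whose left/right ventricles are time-varying
   elastances driven by the myofilament force, yielding pressure–volume
   loops, stroke volume, ejection fraction, stroke work, cardiac output and
   SW/ATP.

Who it is for: computational cardiac electrophysiologists who want a tested,
scriptable reference implementation of the E299V electromechanical phenotype
— APD shortening, alternans suppression, reentry wavelength shortening and
loss of contractility — without a finite-element infrastructure.

## The model in brief

Membrane potential follows

dV/dt = −(I_ion + I_stim)/C_m,  I_ion = I_Na + I_K1 + I_to + I_Kr + I_Ks +
I_CaL + I_NaCa + I_NaK + I_pCa + I_pK + I_bCa + I_bNa,

with tissue coupling dV/dt += D ∇²V (monodomain). The mutation enters only
through I_K1(V−E_K); the three formulations and the reading of their printed
coefficient sets are documented in `docs/methods.md`. Excitation–contraction
coupling is one-way: Ca²⁺ transients drive a regulatory-unit/cross-bridge
cycle (N ↔ P ↔ XB_PreR ↔ XB_PostR with cooperative troponin activation
(TCa)^±7.5), whose normalized force F(t) sets the ventricular elastance
E(t) = E_min + (E_max − E_min)·a(t), a(t) a lagged F(t)/F_ref.

## Worked example

```python
from cardiolab import pace_to_steady_state, measure_apd
from cardiolab.protocols import peak_ik1

for cond in ("WT", "WT_E299V", "E299V"):
    tr = pace_to_steady_state("endo", cond, BCL=600.0, n_beats=50)
    print(f"{cond:9s} APD90 = {measure_apd(tr, -1):6.1f} ms   "
          f"peak IK1 = {peak_ik1(tr, -1):5.2f} pA/pF")
```

prints

```
WT        APD90 =  300.5 ms   peak IK1 =  0.72 pA/pF
WT_E299V  APD90 =  122.9 ms   peak IK1 =  2.23 pA/pF
E299V     APD90 =   66.4 ms   peak IK1 =  4.39 pA/pF
```

— the mutation's signature: each added dose of E299V roughly halves the
endocardial action-potential duration because the de-rectified I_K1 now
carries several pA/pF of repolarizing current throughout the plateau.

The same comparison at the pump level:

```python
from cardiolab import table1_replica
print(table1_replica("runs/table1", n_beats=25))
```

produces (columns abridged)

```
  condition  SV_mL  EF_pct  SW_mmHg_mL  CO_mL_min  peak_LVP_mmHg
0        WT  54.15    51.7      5139.6       5415          109.2
1  WT_E299V  21.12    13.7       799.2       2112           52.4
2     E299V   0.55     0.3         0.1         55           12.2
```

i.e. the heterozygous carrier loses about two thirds of its stroke volume
and the pure mutant effectively stops ejecting, with the PV loops shifting
rightward (rising EDV/ESV) as contractility collapses.

Command-line equivalents:

```bash
cardiolab list-scenarios
cardiolab run sinus-E299V-epi --out runs
cardiolab restitution --condition WT
cardiolab reentry --condition E299V --reduced
cardiolab pump --condition WT_E299V
```

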