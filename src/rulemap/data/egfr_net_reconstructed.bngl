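# Early EGFR signaling model (EGF, EGFR, Grb2, Shc, Sos).
# Synthetic reconstruction: this file rewrites the published 23-rule
# reaction scheme for early events in EGFR signaling from its literature
# description; it is not the original distribution file.  Rate constants
# are per-cell values (copies, seconds).
begin parameters
  NA 6.02e23
  f 1
  Vo f*1.0e-10
  V f*3.0e-12
  EGF_init 20*1e-9*NA*Vo
  EGFR_init f*1.8e5
  Grb2_init f*1.5e5
  Shc_init f*2.7e5
  Sos_init f*6.2e4
  kp1 9.0e7/(NA*Vo)
  km1 0.06
  kp2 1.0e7/(NA*Vo)
  km2 0.1
  kp3 0.5
  km3 4.505
  kp14 3
  km14 0.03
  km16 0.005
  kp9 8.3e6/(NA*V)
  km9 0.05
  kp10 1.1e7/(NA*V)
  km10 0.06
  kp11 1.5e7/(NA*V)
  km11 0.064
  kp13 1.5e7/(NA*V)
  km13 0.6
  kp15 4.5e7/(NA*V)
  km15 0.3
  kp17 8.9e7/(NA*V)
  km17 0.1
  kp18 4.5e7/(NA*V)
  km18 0.3
  kp19 1.55e7/(NA*V)
  km19 0.0214
  kp20 2.9e7/(NA*V)
  km20 0.12
  kp21 8.9e7/(NA*V)
  km21 0.1
  kp22 5.0e7/(NA*V)
  km22 0.0214
  kp23 1.55e7/(NA*V)
  km23 0.0214
  kp24 5.0e7/(NA*V)
  km24 0.0429
  kp25 1.55e7/(NA*V)
  km25 0.0214
end parameters
begin molecule types
  EGF(R)
  EGFR(L,CR1,Y1068~U~P,Y1148~U~P)
  Grb2(SH2,SH3)
  Shc(PTB,Y317~U~P)
  Sos(PR)
end molecule types
begin seed species
  EGF(R) EGF_init
  EGFR(L,CR1,Y1068~U,Y1148~U) EGFR_init
  Grb2(SH2,SH3) Grb2_init
  Shc(PTB,Y317~U) Shc_init
  Sos(PR) Sos_init
end seed species
begin observables
  Molecules EGFR_total EGFR()
  Molecules Dimers EGFR(CR1!+)
  Molecules RP EGFR(Y1068~P!?) EGFR(Y1148~P!?)
  Molecules Shc_P Shc(Y317~P!?)
  Molecules Sos_recruited EGFR().Sos()
end observables
begin reaction rules
# ligand binding to receptor monomers
  R1: EGFR(L,CR1) + EGF(R) <-> EGFR(L!1,CR1).EGF(R!1) kp1, km1
# aggregation of ligand-bound monomers
  R2: EGFR(L!+,CR1) + EGFR(L!+,CR1) <-> EGFR(L!+,CR1!1).EGFR(L!+,CR1!1) kp2, km2
# transphosphorylation of EGFR by the partner receptor kinase
  R3: EGFR(CR1!+,Y1068~U) -> EGFR(CR1!+,Y1068~P) kp3
  R4: EGFR(CR1!+,Y1148~U) -> EGFR(CR1!+,Y1148~P) kp3
# dephosphorylation of unprotected receptor sites
  R5: EGFR(Y1068~P) -> EGFR(Y1068~U) km3
  R6: EGFR(Y1148~P) -> EGFR(Y1148~U) km3
# Shc transphosphorylation in dimers; dephosphorylation of bound Shc
  R7: EGFR(CR1!+,Y1148~P!1).Shc(PTB!1,Y317~U) -> EGFR(CR1!+,Y1148~P!1).Shc(PTB!1,Y317~P) kp14
  R8: Shc(PTB!+,Y317~P) -> Shc(PTB!+,Y317~U) km14
# Y1068 activity: Grb2 and Grb2-Sos binding, Sos recruitment
  R9: EGFR(Y1068~P) + Grb2(SH2,SH3) <-> EGFR(Y1068~P!1).Grb2(SH2!1,SH3) kp9, km9
  R10: EGFR(Y1068~P) + Grb2(SH2,SH3!1).Sos(PR!1) <-> EGFR(Y1068~P!2).Grb2(SH2!2,SH3!1).Sos(PR!1) kp10, km10
  R11: EGFR(Y1068~P!1).Grb2(SH2!1,SH3) + Sos(PR) <-> EGFR(Y1068~P!1).Grb2(SH2!1,SH3!2).Sos(PR!2) kp11, km11
# Y1148 activity: Shc binding in all its cytosolic forms
  R12: EGFR(Y1148~P) + Shc(PTB,Y317~U) <-> EGFR(Y1148~P!1).Shc(PTB!1,Y317~U) kp13, km13
  R13: EGFR(Y1148~P) + Shc(PTB,Y317~P) <-> EGFR(Y1148~P!1).Shc(PTB!1,Y317~P) kp15, km15
  R14: EGFR(Y1148~P) + Shc(PTB,Y317~P!1).Grb2(SH2!1,SH3) <-> EGFR(Y1148~P!2).Shc(PTB!2,Y317~P!1).Grb2(SH2!1,SH3) kp18, km18
  R15: EGFR(Y1148~P) + Shc(PTB,Y317~P!1).Grb2(SH2!1,SH3!2).Sos(PR!2) <-> EGFR(Y1148~P!3).Shc(PTB!3,Y317~P!1).Grb2(SH2!1,SH3!2).Sos(PR!2) kp20, km20
# Grb2 and Grb2-Sos binding to receptor-bound phospho-Shc
  R16: Shc(PTB!+,Y317~P) + Grb2(SH2,SH3) <-> Shc(PTB!+,Y317~P!1).Grb2(SH2!1,SH3) kp17, km17
  R17: Shc(PTB!+,Y317~P) + Grb2(SH2,SH3!1).Sos(PR!1) <-> Shc(PTB!+,Y317~P!2).Grb2(SH2!2,SH3!1).Sos(PR!1) kp24, km24
# Sos recruitment to receptor-bound Shc-Grb2
  R18: Shc(PTB!+,Y317~P!1).Grb2(SH2!1,SH3) + Sos(PR) <-> Shc(PTB!+,Y317~P!1).Grb2(SH2!1,SH3!2).Sos(PR!2) kp19, km19
# cytosolic complex formation
  R19: Shc(PTB,Y317~P) + Grb2(SH2,SH3) <-> Shc(PTB,Y317~P!1).Grb2(SH2!1,SH3) kp21, km21
  R20: Shc(PTB,Y317~P) + Grb2(SH2,SH3!1).Sos(PR!1) <-> Shc(PTB,Y317~P!2).Grb2(SH2!2,SH3!1).Sos(PR!1) kp23, km23
  R21: Shc(PTB,Y317~P!1).Grb2(SH2!1,SH3) + Sos(PR) <-> Shc(PTB,Y317~P!1).Grb2(SH2!1,SH3!2).Sos(PR!2) kp25, km25
  R22: Grb2(SH2,SH3) + Sos(PR) <-> Grb2(SH2,SH3!1).Sos(PR!1) kp22, km22
# cytosolic Shc dephosphorylation
  R23: Shc(PTB,Y317~P) -> Shc(PTB,Y317~U) km16
end reaction rules
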