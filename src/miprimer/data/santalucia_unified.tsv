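# Unified nearest-neighbor parameters for DNA/DNA duplexes (SantaLucia 1998).
# dH in kcal/mol, dS in cal/(mol K), dG37 = dH - 310.15*dS/1000 in kcal/mol.
# Steps are written 5'->3' on the top strand; the complementary step shares
# the same values (e.g. AA == TT read on the other strand).
step	dH	dS	dG37
AA	-7.9	-22.2	-1.00
AT	-7.2	-20.4	-0.88
TA	-7.2	-21.3	-0.58
CA	-8.5	-22.7	-1.45
GT	-8.4	-22.4	-1.44
CT	-7.8	-21.0	-1.28
GA	-8.2	-22.2	-1.30
CG	-10.6	-27.2	-2.17
GC	-9.8	-24.4	-2.24
GG	-8.0	-19.9	-1.84
TT	-7.9	-22.2	-1.00
TG	-8.5	-22.7	-1.45
AC	-8.4	-22.4	-1.44
AG	-7.8	-21.0	-1.28
TC	-8.2	-22.2	-1.30
CC	-8.0	-19.9	-1.84
init_GC	0.1	-2.8	0.98
init_AT	2.3	4.1	1.03
symmetry	0.0	-1.4	0.43
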