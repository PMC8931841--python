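term,class,seasonality_p,p_two_spring,p_two_summer,p_two_autumn,p_two_winter,p_one_spring,p_one_summer,p_one_autumn,p_one_winter
bug bite,communicable,<.001,.54,.43,.06,<.001,.41,>.99,.05,<.001
chicken pox,communicable,.06,<.001,<.001,<.001,<.001,<.001,.009,<.001,<.001
chlamydia,communicable,.83,<.001,<.001,<.001,<.001,<.001,<.001,<.001,<.001
cold medicine,communicable,<.001,<.001,.003,<.001,<.001,<.001,.004,<.001,<.001
conjunctivitis,communicable,<.001,<.001,<.001,<.001,<.001,<.001,<.001,<.001,<.001
ear infection,communicable,<.001,<.001,.05,.001,<.001,<.001,.05,<.001,<.001
fifth disease,communicable,<.001,<.001,.03,.02,<.001,<.001,.03,.02,<.001
german measles,communicable,.38,.71,.91,.81,.21,.97,.90,.63,.14
gonorrhea,communicable,.48,<.001,.01,<.001,.02,<.001,.01,<.001,.01
HIV,communicable,.05,<.001,<.001,<.001,<.001,<.001,<.001,<.001,<.001
hpv,communicable,.62,<.001,.15,.09,<.001,<.001,.14,.07,<.001
impetigo,communicable,.03,<.001,<.001,<.001,<.001,<.001,<.001,<.001,<.001
lice,communicable,<.001,<.001,<.001,<.001,<.001,<.001,<.001,<.001,<.001
measles,communicable,.01,.10,.01,.06,<.001,.08,.01,.05,<.001
meningitis,communicable,.62,<.001,.008,<.001,<.001,<.001,.008,<.001,<.001
mononucleosis,communicable,.25,<.001,.77,.55,<.001,<.001,.75,.44,<.001
mumps,communicable,.62,.01,.004,.002,<.001,.01,.004,.002,<.001
pertussis,communicable,.64,<.001,.84,.36,.003,<.001,>.99,.28,.002
pink eye,communicable,<.001,<.001,<.001,<.001,<.001,<.001,<.001,<.001,<.001
ringworm,communicable,<.001,.04,<.001,<.001,<.001,.03,<.001,<.001,<.001
rubella,communicable,.01,.15,.69,.79,.01,.12,.65,.62,.008
salmonella,communicable,.62,.25,.45,.43,<.001,.20,>.99,.35,<.001
scabies,communicable,.11,<.001,.02,<.001,<.001,<.001,.02,<.001,<.001
shingles treatment,communicable,.19,.15,.47,.33,.93,>.99,>.99,>.99,.62
std,communicable,.02,<.001,<.001,.005,<.001,<.001,<.001,.004,<.001
stomach flu,communicable,<.001,<.001,<.001,<.001,<.001,<.001,<.001,<.001,<.001
strep throat,communicable,<.001,<.001,<.001,<.001,<.001,<.001,<.001,<.001,<.001
syphilis,communicable,.88,.22,.81,.36,.93,.17,.78,.29,.70
tuberculosis,communicable,.05,.53,.04,.74,.02,.40,>.99,.60,.02
arthritis,noncommunicable,.26,<.001,.33,.65,.07,<.001,>.99,>.99,.05
broken bone,noncommunicable,.23,<.001,.03,.53,.004,<.001,.03,.43,.003
burning eyes,noncommunicable,>.99,<.001,.002,.04,<.001,>.99,>.99,>.99,>.99
cancer,noncommunicable,.26,<.001,<.001,.007,<.001,<.001,<.001,.006,<.001
cataracts,noncommunicable,.97,<.001,.33,.50,.12,<.001,.30,.41,.08
claritin,noncommunicable,<.001,.50,.63,.59,.002,.39,>.99,.46,.002
corneal ulcer,noncommunicable,.26,.10,.04,.74,.86,.08,.03,.60,.56
diabetes,noncommunicable,.01,<.001,.84,.20,.93,<.001,>.99,.16,.70
diabetic retinopathy,noncommunicable,.88,.15,.70,.43,.40,.12,>.99,>.99,.26
dry eyes,noncommunicable,.13,.02,.93,.04,<.001,.02,>.99,>.99,>.99
eczema,noncommunicable,<.001,.30,.19,.04,.003,.24,.18,.03,.002
glaucoma,noncommunicable,.41,<.001,.42,.36,.03,<.001,.38,.29,.02
heart attack,noncommunicable,.01,.15,.41,.34,.03,.12,.37,.28,.02
high blood pressure,noncommunicable,<.001,<.001,.91,.66,.29,<.001,.89,>.99,.20
itchy eyes,noncommunicable,<.001,<.001,.003,.10,.22,>.99,>.99,>.99,>.99
macular degeneration,noncommunicable,.78,<.001,.42,.36,.08,<.001,>.99,>.99,.05
memory loss,noncommunicable,.92,<.001,.81,.79,.93,<.001,>.99,.62,.71
pollen,noncommunicable,<.001,<.001,<.001,<.001,.28,>.99,>.99,>.99,>.99
pregnant,noncommunicable,.05,.38,.43,.79,.80,.30,.38,.62,.53
red eyes,noncommunicable,.19,.004,.72,.86,.59,>.99,>.99,.66,.39
sore eyes,noncommunicable,.83,.51,.22,.04,.12,.39,>.99,>.99,>.99
stroke symptoms,noncommunicable,<.001,.25,.91,.36,.06,>.99,>.99,>.99,>.99
toothache,noncommunicable,.62,.06,.41,.13,.34,>.99,.37,.11,.23
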