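# Oil palm (Elaeis guineensis) ecoclimatic parameter set.
# Temperatures degC; soil moisture as fraction of holding capacity;
# rates per week (cold/dry rates negative as conventionally printed).

DV0 = 19.0     # limiting low temperature
DV1 = 24.0     # lower optimal temperature
DV2 = 28.0     # upper optimal temperature
DV3 = 36.0     # limiting high temperature

SM0 = 0.4      # limiting low soil moisture
SM1 = 0.6      # lower optimal soil moisture
SM2 = 1.6      # upper optimal soil moisture
SM3 = 2.0      # limiting high soil moisture

TTCS = 15.0    # cold stress temperature threshold
THCS = -0.005  # cold stress temperature rate
DTCS = 20.0    # minimum degree-day cold stress threshold (degC days / week)
DHCS = -0.0005 # degree-day cold stress rate

TTHS = 36.0    # heat stress temperature threshold
THHS = 0.001   # heat stress temperature rate

SMDS = 0.4     # dry stress threshold
HDS = -0.007   # dry stress rate

SMWS = 2.0     # wet stress threshold
HWS = 0.0023   # wet stress rate

PDD = 1500.0   # degree-day threshold (annual heat sum above DV0)

# Hydrology (bucket model) settings; not species-table values.
soil_capacity = 100.0  # mm
k_et = 1.0             # mm per degC per day, per unit soil-moisture fraction
sm_cap = 2.5           # bucket ceiling, fraction of soil_capacity
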