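patient_id,no_change,response,risk_group
P01,stable_increased,failure,intermediate
P02,stable_increased,failure,intermediate
P03,stable_increased,failure,intermediate
P04,stable_increased,failure,intermediate
P05,stable_increased,failure,poor
P06,stable_increased,failure,poor
P07,stable_increased,failure,favorable
P08,stable_increased,failure,poor
P09,stable_increased,response,favorable
P10,stable_increased,response,favorable
P11,stable_increased,response,poor
P12,decreased,failure,intermediate
P13,decreased,failure,poor
P14,decreased,response,intermediate
P15,decreased,response,intermediate
P16,decreased,response,intermediate
P17,decreased,response,favorable
P18,decreased,response,favorable
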