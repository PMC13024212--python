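metabolite,condition,H,M_initial_mM,M_final_mM,delta_t_h,v_exp_mM_per_h,sd,v_model_mM_per_h,rel_dev_percent
cysteine,ES2_hypoxia,1,0.2626,0.0671,24,0.0081,,0.0076,6.2
glutamate,ES2_hypoxia,1,0.0103,0.1470,24,-0.0057,,-0.0053,7.0
glutamine,ES2_hypoxia,1,2.3194,0.7627,24,0.0652,,0.0619,5.1
methionine,ES2_hypoxia,1,0.1561,0.0970,24,0.0025,,0.0026,3.8
glucose,ES2_hypoxia,1,20.3972,4.6909,24,0.6544,,0.6210,5.1
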