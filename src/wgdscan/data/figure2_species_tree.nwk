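((S_camelus,T_guttatus),(((G_gallus,M_gallopavo),A_domestica),(((C_livia,(P_guturalis,M_unicolor)),(P_ruber,P_cristatus)),((A_carolinensis,(C_pelagica,C_anna)),((T_erythrolophus,C_macqueenii),((O_hoazin,C_vociferous),((E_helias,P_lepturus),((G_stellata,(P_adeliae,(F_glacialis,(P_crispus,(E_garzetta,(N_nippon,P_carbo)))))),((H_albicilla,T_alba),((C_striatus,(L_discolor,(A_vittatum,(B_silvestris,(M_numbicus,P_pubescens))))),(C_cristata,(F_peregrinus,((N_notabilis,M_undulatus),(A_chloris,(M_vitellinus,(C_brachyrhynchos,(T_guttata,G_fortis)))))))))))))))));
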