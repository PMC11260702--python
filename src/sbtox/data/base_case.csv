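id,group,base_value,unit,family,dist_params,source
tox_grade1_imrt_igrt,transition,5.088,%,degenerate,,phase II IMRT/IGRT late-toxicity trial
tox_grade2_imrt_igrt,transition,1.594,%,degenerate,,phase II IMRT/IGRT late-toxicity trial
tox_grade3_imrt_igrt,transition,0.658,%,degenerate,,phase II IMRT/IGRT late-toxicity trial
tox_grade4_imrt_igrt,transition,0.216,%,degenerate,,phase II IMRT/IGRT late-toxicity trial
tox_grade1_imrt,transition,7.491,%,degenerate,,derived: IMRT/IGRT row x NTCP ratio
tox_grade2_imrt,transition,2.346,%,degenerate,,derived: IMRT/IGRT row x NTCP ratio
tox_grade3_imrt,transition,0.969,%,degenerate,,derived: IMRT/IGRT row x NTCP ratio
tox_grade4_imrt,transition,0.317,%,degenerate,,derived: IMRT/IGRT row x NTCP ratio
tox_grade1_3dcrt,transition,11.166,%,degenerate,,derived: IMRT/IGRT row x NTCP ratio
tox_grade2_3dcrt,transition,3.497,%,degenerate,,derived: IMRT/IGRT row x NTCP ratio
tox_grade3_3dcrt,transition,1.444,%,degenerate,,derived: IMRT/IGRT row x NTCP ratio
tox_grade4_3dcrt,transition,0.473,%,degenerate,,derived: IMRT/IGRT row x NTCP ratio
ntcp_imrt_igrt,transition,18.0,%,degenerate,,NTCP model for small-bowel complications
ntcp_imrt,transition,26.5,%,degenerate,,NTCP model for small-bowel complications
ntcp_3dcrt,transition,39.5,%,degenerate,,NTCP model for small-bowel complications
tox_event_uncertainty,transition,1.0,dimensionless,beta,alpha=50;beta=50;scale=2,joint uncertainty on the grade-probability vector
p_mgmt_loperamide,treatment,92.80,%,beta,alpha=41.00;beta=22.00,antidiarrheal management study
p_second_line_ab,treatment,44.44,%,beta,alpha=32.00;beta=40.00,second-line management study
p_second_line_bas,treatment,55.56,%,beta,alpha=40.00;beta=32.00,second-line management study
p_mgmt_ab,treatment,41.85,%,beta,alpha=15.00;beta=17.00,second-line management study
p_mgmt_bas,treatment,30.87,%,beta,alpha=14.00;beta=26.00,second-line management study
p_surgery_after_hosp,treatment,22.80,%,beta,alpha=61.00;beta=90.00,non-operative small-bowel obstruction study
p_supportive_after_hosp,treatment,77.20,%,beta,alpha=90.00;beta=61.00,non-operative small-bowel obstruction study
p_mgmt_after_surgery,treatment,96.22,%,beta,alpha=32.64;beta=15.36,small-bowel surgery outcome study
p_death_after_surgery,treatment,3.783,%,beta,alpha=32.64;beta=15.36,small-bowel surgery outcome study
p_mgmt_after_supportive,treatment,99.16,%,beta,alpha=167775;beta=2845,supportive-care outcome study
p_death_after_supportive,treatment,0.837,%,beta,alpha=2845;beta=167775,supportive-care outcome study
p_rec1_surgery,recurrence,1.181,%,beta,alpha=8.277;beta=65.62,small-bowel obstruction recurrence study
p_rec1_supportive,recurrence,2.106,%,beta,alpha=42.61;beta=179.7,small-bowel obstruction recurrence study
p_rec2_surgery,recurrence,2.124,%,beta,alpha=1.174;beta=4.904,small-bowel obstruction recurrence study
p_rec2_supportive,recurrence,4.852,%,beta,alpha=63.86;beta=99.09,small-bowel obstruction recurrence study
p_rec3_surgery,recurrence,1.965,%,beta,alpha=0.062;beta=0.283,small-bowel obstruction recurrence study
p_rec3_supportive,recurrence,6.332,%,beta,alpha=41.77;beta=45.23,small-bowel obstruction recurrence study
p_rec4_surgery,recurrence,3.678,%,beta,alpha=63.86;beta=99.09,small-bowel obstruction recurrence study
p_rec4_supportive,recurrence,7.726,%,beta,alpha=0.057;beta=0.124,small-bowel obstruction recurrence study
cost_loperamide_unit,direct_cost,0.043,EUR,gamma,kappa=100.0;theta=4.312e-4,national formulary
cost_ab_unit,direct_cost,0.011,EUR,gamma,kappa=100.0;theta=12.70e-4,national formulary
cost_bas_unit,direct_cost,0.127,EUR,gamma,kappa=100.0;theta=1.082e-4,national formulary
cost_hosp_surgery,direct_cost,11495.840,EUR,gamma,kappa=100.0;theta=115.0,national inpatient cost database
cost_hosp_supportive,direct_cost,4760.970,EUR,gamma,kappa=100.0;theta=47.61,national inpatient cost database
activity_rate,indirect_cost,75.10,%,beta,alpha=75.10;beta=24.90,national labour-market statistics
wage_daily,indirect_cost,250.118,EUR,gamma,kappa=100.0;theta=2.501,national wage statistics
wage_annual,indirect_cost,55025.900,EUR,gamma,kappa=100.0;theta=550.3,national wage statistics
sick_days_event,indirect_cost,14.550,days,lognormal,mu_log=2.678,inflammatory bowel disease absenteeism study
sick_days_management,indirect_cost,9.650,days,lognormal,mu_log=2.677,inflammatory bowel disease absenteeism study
sick_leave_hosp_factor,indirect_cost,0.500,dimensionless,lognormal,mu_log=-0.693,expert opinion
disutility_pharma,utility,-24.7,%,degenerate,,Crohn's disease utility study (proxy)
disutility_supportive,utility,-32.3,%,degenerate,,Crohn's disease utility study (proxy)
disutility_surgery,utility,-38.7,%,degenerate,,Crohn's disease utility study (proxy)
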