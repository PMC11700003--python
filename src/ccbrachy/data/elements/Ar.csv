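# element,Ar,Z,18,A,39.948
energy_MeV,mu_over_rho_cm2_g,muen_over_rho_cm2_g,frac_photoelectric,frac_incoherent,frac_coherent
1.000000e-03,5.3110936553e+04,5.3045364126e+04,9.987653620639e-01,3.385572462374e-06,1.231252363655e-03
1.500000e-03,1.7923139703e+04,1.7903619864e+04,9.989108849291e-01,1.001287283001e-05,1.079102198110e-03
2.000000e-03,8.0377133618e+03,8.0279135697e+03,9.987806871593e-01,2.228433166080e-05,1.197028509040e-03
3.000000e-03,2.5067332723e+03,2.5015335628e+03,9.979252903719e-01,7.117877132493e-05,2.003530856821e-03
4.000000e-03,1.0723632338e+03,1.0688468331e+03,9.967196109991e-01,1.657499882259e-04,3.114639012718e-03
5.000000e-03,5.4913053943e+02,5.4647874986e+02,9.951678417280e-01,3.224533215864e-04,4.509704950398e-03
6.000000e-03,3.0820008306e+02,3.0610593218e+02,9.931986714242e-01,5.723568035962e-04,6.228971772228e-03
8.000000e-03,1.3075742554e+02,1.2934377025e+02,9.891684527843e-01,1.338990480529e-03,9.492556735133e-03
1.000000e-02,6.5532071782e+01,6.4466530442e+01,9.836903937111e-01,2.651999748851e-03,1.365760654004e-02
1.500000e-02,1.8895351858e+01,1.8245659518e+01,9.653671796067e-01,9.032292950138e-03,2.560052744319e-02
2.000000e-02,7.8237459816e+00,7.3543117422e+00,9.392261035868e-01,2.143349578455e-02,3.934040062866e-02
3.000000e-02,2.3279678594e+00,2.0179681773e+00,8.632125752835e-01,6.964419170678e-02,6.714323300971e-02
4.000000e-02,1.0444118944e+00,8.0427601645e-01,7.600190539921e-01,1.503622135924e-01,8.961873241546e-02
5.000000e-02,5.9904703742e-01,3.9705251288e-01,6.422793082681e-01,2.543446309832e-01,1.033760607487e-01
6.000000e-02,4.0505152492e-01,2.2648750966e-01,5.249341493857e-01,3.655175547210e-01,1.095482958932e-01
8.000000e-02,2.4944496369e-01,9.9675247547e-02,3.336789054304e-01,5.627089976155e-01,1.036120969541e-01
1.000000e-01,1.9047890139e-01,5.8635863149e-02,2.109623123187e-01,7.019509891289e-01,8.708669855235e-02
1.500000e-01,1.3871337660e-01,3.2606598256e-02,7.751076356105e-02,8.677745413051e-01,5.471469513384e-02
2.000000e-01,1.1870832510e-01,2.7982609268e-02,3.470061307218e-02,9.291568026157e-01,3.614258431211e-02
3.000000e-01,9.8743094338e-02,2.6750640047e-02,8.998329949054e-03,9.712921284168e-01,1.970954163415e-02
4.000000e-01,8.7213941456e-02,2.6762711979e-02,1.791859846731e-03,9.852864378020e-01,1.292170235131e-02
5.000000e-01,7.9478763473e-02,2.6785335216e-02,0.000000000000e+00,9.872450615675e-01,1.275493843251e-02
6.000000e-01,7.3262358210e-02,2.6676149022e-02,0.000000000000e+00,9.907562077284e-01,9.243792271551e-03
8.000000e-01,6.4268008981e-02,2.6054594742e-02,0.000000000000e+00,9.920349980522e-01,7.965001947781e-03
1.000000e+00,5.7876921870e-02,2.5219321223e-02,0.000000000000e+00,9.902231261052e-01,9.776873894811e-03
1.250000e+00,5.1774931720e-02,2.4110494320e-02,0.000000000000e+00,9.895904138894e-01,1.040958611063e-02
1.500000e+00,4.7477693961e-02,2.3031017134e-02,0.000000000000e+00,9.806094690140e-01,1.939053098595e-02
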